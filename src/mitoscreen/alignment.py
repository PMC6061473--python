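"""Global pairwise alignment, gap-aware coordinate lifting, consensus calling.

The screen needs only rCRS↔sequence homology, which either comes for free
from a user-supplied multiple alignment containing the rCRS row, or is
established here by anchoring each species sequence to the rCRS gene with a
deterministic Needleman–Wunsch global alignment (match +1, mismatch −1,
linear gap −2 by default; N and IUPAC ambiguity codes score 0 against
anything).  Traceback ties break diagonal > up (gap in query) > left (gap in
reference) so column maps are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .reference_model import GeneRegion, MitoscreenError
from .sequence_io import SpeciesSequenceSet

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "HomologyMap",
    "needleman_wunsch",
    "build_homology_map",
    "consensus_sequence",
    "IUPAC_FOR_BASES",
]

GAP = "-"

IUPAC_FOR_BASES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass(frozen=True)
class PairwiseAlignment:
    ref_row: str
    query_row: str
    score: int

    def __post_init__(self) -> None:
        if len(self.ref_row) != len(self.query_row):
            raise MitoscreenError("alignment rows have different lengths")


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(codes, ambiguous flag); ambiguous bases score 0 against anything."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes, codes < 0


def needleman_wunsch(
    ref: str, query: str, scheme: ScoringScheme = ScoringScheme()
) -> PairwiseAlignment:
    """One optimal global alignment of ``query`` against ``ref``.

    Linear gap penalties; deterministic traceback (diagonal preferred, then
    gap-in-query, then gap-in-reference).
    """
    if not ref or not query:
        raise MitoscreenError("cannot align an empty sequence")
    n, m = len(ref), len(query)
    rc, ramb = _encode(ref)
    qc, qamb = _encode(query)
    g = scheme.gap
    jr = np.arange(m + 1, dtype=np.int64)
    gj = g * jr
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    H[0] = gj
    # per-row substitution scores; the in-row "left" dependency is resolved by
    # a running-max trick valid for linear gaps:
    #   H[i,j] = max_{k<=j} (A[k] + g*(j-k)),  A = best of diagonal/up moves
    for i in range(1, n + 1):
        if ramb[i - 1]:
            s = np.zeros(m, dtype=np.int64)
        else:
            s = np.where(qamb, 0,
                         np.where(qc == rc[i - 1], scheme.match, scheme.mismatch)
                         ).astype(np.int64)
        A = np.empty(m + 1, dtype=np.int64)
        A[0] = H[i - 1, 0] + g
        np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + g, out=A[1:])
        H[i] = np.maximum.accumulate(A - gj) + gj
    # traceback
    i, j = n, m
    ref_row: list[str] = []
    query_row: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if i > 0 and j > 0:
            if ramb[i - 1] or qamb[j - 1]:
                s = 0
            elif rc[i - 1] == qc[j - 1]:
                s = scheme.match
            else:
                s = scheme.mismatch
            if h == H[i - 1, j - 1] + s:
                ref_row.append(ref[i - 1])
                query_row.append(query[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + g:
            ref_row.append(ref[i - 1])
            query_row.append(GAP)
            i -= 1
            continue
        ref_row.append(GAP)
        query_row.append(query[j - 1])
        j -= 1
    return PairwiseAlignment(
        "".join(reversed(ref_row)), "".join(reversed(query_row)), int(H[n, m])
    )


# ---------------------------------------------------------------------------
# Homology maps
# ---------------------------------------------------------------------------


class HomologyMap:
    """Correspondence between rCRS gene positions and a sequence set.

    For every non-reference sequence, maps each rCRS position of the gene to
    the homologous 1-based position in that (ungapped) sequence, or None where
    the sequence is gapped; ``column_of`` additionally gives the 1-based
    alignment column for aligned input.
    """

    def __init__(
        self,
        gene: GeneRegion,
        seq_positions: dict[str, dict[int, Optional[int]]],
        seq_bases: dict[str, dict[int, Optional[str]]],
        columns: Optional[dict[int, int]] = None,
    ):
        self.gene = gene
        self._seq_positions = seq_positions
        self._seq_bases = seq_bases
        self._columns = columns
        for sid, mapping in seq_positions.items():
            imgs = [p for p in mapping.values() if p is not None]
            if any(b >= a for a, b in zip(imgs[1:], imgs)):
                raise MitoscreenError(
                    f"{sid}: homology map not strictly increasing"
                )

    @property
    def sequence_ids(self) -> list[str]:
        return list(self._seq_positions)

    def position_in(self, sequence_id: str, pos: int) -> Optional[int]:
        self._check(pos)
        return self._seq_positions[sequence_id][pos]

    def base_at(self, sequence_id: str, pos: int) -> Optional[str]:
        """Residue of the sequence at the site homologous to rCRS ``pos``;
        None where the sequence is gapped."""
        self._check(pos)
        return self._seq_bases[sequence_id][pos]

    def column_of(self, pos: int) -> int:
        if self._columns is None:
            raise MitoscreenError("column map only available for aligned input")
        self._check(pos)
        return self._columns[pos]

    def _check(self, pos: int) -> None:
        if not self.gene.contains(pos):
            raise MitoscreenError(
                f"position {pos} outside {self.gene.name} "
                f"[{self.gene.start},{self.gene.end}]"
            )


def _lift_from_rows(ref_row: str, query_row: str, start: int):
    """Per-position map and bases from two gapped alignment rows."""
    pos_map: dict[int, Optional[int]] = {}
    base_map: dict[int, Optional[str]] = {}
    ref_pos = start - 1
    q_pos = 0
    for r, q in zip(ref_row, query_row):
        if q != GAP:
            q_pos += 1
        if r != GAP:
            ref_pos += 1
            if q != GAP:
                pos_map[ref_pos] = q_pos
                base_map[ref_pos] = q
            else:
                pos_map[ref_pos] = None
                base_map[ref_pos] = None
    return pos_map, base_map


def build_homology_map(
    sset: SpeciesSequenceSet,
    gene: GeneRegion,
    ref_gene_seq: Optional[str] = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> HomologyMap:
    """Map rCRS gene positions onto every non-reference sequence of ``sset``.

    Aligned input is anchored on the embedded rCRS row (error if absent);
    unaligned input is anchored sequence-by-sequence with
    :func:`needleman_wunsch` against ``ref_gene_seq``.
    """
    seq_positions: dict[str, dict[int, Optional[int]]] = {}
    seq_bases: dict[str, dict[int, Optional[str]]] = {}
    if sset.aligned:
        ref_entry = sset.reference_entry
        if ref_entry is None:
            raise MitoscreenError(
                f"{gene.name}: aligned input has no reference (rCRS) row"
            )
        ref_row = ref_entry.residues
        ungapped = ref_row.replace(GAP, "")
        if len(ungapped) != gene.length:
            raise MitoscreenError(
                f"{gene.name}: reference row has {len(ungapped)} bases, "
                f"gene interval has {gene.length}"
            )
        if ref_gene_seq is not None and ungapped != ref_gene_seq.upper():
            raise MitoscreenError(
                f"{gene.name}: embedded rCRS row disagrees with the supplied "
                "reference gene sequence"
            )
        columns: dict[int, int] = {}
        k = gene.start - 1
        for col, r in enumerate(ref_row, start=1):
            if r != GAP:
                k += 1
                columns[k] = col
        for entry in sset.non_reference_entries():
            pos_map, base_map = _lift_from_rows(ref_row, entry.residues, gene.start)
            seq_positions[entry.sequence_id] = pos_map
            seq_bases[entry.sequence_id] = base_map
        return HomologyMap(gene, seq_positions, seq_bases, columns)
    if ref_gene_seq is None:
        raise MitoscreenError(
            f"{gene.name}: unaligned input needs the reference gene sequence "
            "for pairwise anchoring"
        )
    if len(ref_gene_seq) != gene.length:
        raise MitoscreenError(
            f"{gene.name}: reference length {len(ref_gene_seq)} != "
            f"interval length {gene.length}"
        )
    for entry in sset.non_reference_entries():
        aln = needleman_wunsch(ref_gene_seq.upper(), entry.residues, scheme)
        pos_map, base_map = _lift_from_rows(aln.ref_row, aln.query_row, gene.start)
        seq_positions[entry.sequence_id] = pos_map
        seq_bases[entry.sequence_id] = base_map
    return HomologyMap(gene, seq_positions, seq_bases, None)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def consensus_sequence(
    sset: SpeciesSequenceSet, tie_rule: str = "alphabetical"
) -> str:
    """Majority-rule consensus of an aligned set (typically one species).

    Per column the most frequent non-gap residue wins; a gap is emitted only
    where every row is gapped.  Ties resolve alphabetically (default) or to
    the IUPAC code of the tied bases (``tie_rule="iupac"``).
    """
    if not sset.entries:
        raise MitoscreenError("cannot take the consensus of an empty set")
    if not sset.aligned:
        raise MitoscreenError("consensus requires aligned input")
    if tie_rule not in ("alphabetical", "iupac"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    rows = [e.residues for e in sset.entries]
    width = len(rows[0])
    out = []
    for col in range(width):
        counts = Counter(row[col] for row in rows if row[col] != GAP)
        if not counts:
            out.append(GAP)
            continue
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) == 1 or tie_rule == "alphabetical":
            out.append(tied[0])
        else:
            key = frozenset(b for b in tied if b in "ACGT")
            out.append(IUPAC_FOR_BASES.get(key, "N"))
    return "".join(out)
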