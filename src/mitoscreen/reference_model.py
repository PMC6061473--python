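"""rCRS coordinate system, complex I gene map, codon addressing and translation.

Positions throughout are 1-based inclusive rCRS coordinates, matching the
clinical ``m.NNNN`` notation (NC_012920.1 numbering).  Reference gene
sequences are stored in heavy-strand orientation; for the one light-strand
complex I gene (ND6) codon extraction reverse-complements on the fly so that
translation always happens on the coding strand.

The default genetic code is the vertebrate mitochondrial table (NCBI table 2:
ATA=Met, TGA=Trp, AGA/AGG=stop), built from Biopython's codon tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "MitoscreenError",
    "InvalidCoordinateError",
    "OutOfGeneError",
    "IncompleteCodonError",
    "UntranslatableCodonError",
    "ReferenceMismatchError",
    "GeneRegion",
    "CodonAddress",
    "GeneticCode",
    "VERTEBRATE_MITO_CODE",
    "DATA_DIR",
    "reverse_complement",
    "complement_base",
    "load_gene_map",
    "default_gene_map",
    "genes_for_position",
    "codon_address",
    "codon_on_coding_strand",
    "translate_codon",
    "human_aa_change",
    "next_initiation_codon",
]

DATA_DIR = Path(__file__).parent / "data"

STOP = "*"

_COMPLEMENT = str.maketrans(
    "ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn"
)


class MitoscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidCoordinateError(MitoscreenError):
    """A position is outside the valid rCRS coordinate domain."""


class OutOfGeneError(MitoscreenError):
    """A position does not fall inside the queried gene interval."""


class IncompleteCodonError(MitoscreenError):
    """The position belongs to an incomplete (polyA-completed) terminal codon."""


class UntranslatableCodonError(MitoscreenError):
    """A codon contains gaps or ambiguous bases and cannot be translated."""


class ReferenceMismatchError(MitoscreenError):
    """The stated reference allele disagrees with the reference sequence."""


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRegion:
    """An rCRS gene interval.

    ``start``/``end`` are 1-based inclusive heavy-strand coordinates; genes on
    the light strand (ND6) are read 3'→5' relative to rCRS numbering, i.e. the
    coding frame starts at ``end`` and runs downward.  ``incomplete_terminal``
    marks genes whose stop codon is completed by polyadenylation of the mRNA;
    the truncated tail is excluded from codon addressing.
    """

    name: str
    start: int
    end: int
    strand: str  # "heavy" | "light"
    incomplete_terminal: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidCoordinateError(
                f"{self.name}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("heavy", "light"):
            raise InvalidCoordinateError(f"{self.name}: bad strand {self.strand!r}")
        trailing = self.length % 3
        if trailing and not self.incomplete_terminal:
            raise InvalidCoordinateError(
                f"{self.name}: length {self.length} is not a whole number of "
                "codons and the region is not flagged incomplete_terminal"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_complete_codons(self) -> int:
        return self.length // 3

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class CodonAddress:
    """Location of an rCRS position within a gene's coding frame.

    ``rcrs_positions`` spell the containing codon in coding-strand order:
    ascending consecutive for heavy-strand genes, descending for light-strand
    genes.  ``within_codon_offset`` is the 1-based slot of the queried position
    in that triple.
    """

    gene: str
    codon_index: int
    within_codon_offset: int
    rcrs_positions: tuple[int, int, int]


@dataclass(frozen=True)
class GeneticCode:
    """A total codon → amino-acid mapping over the 64 unambiguous codons."""

    table_id: str
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.table_id!r} has {len(self.codon_to_aa)} "
                "entries, expected 64"
            )


def _build_vertebrate_mito_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[2]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return GeneticCode("vertebrate mitochondrial", mapping)


VERTEBRATE_MITO_CODE = _build_vertebrate_mito_code()


# ---------------------------------------------------------------------------
# Gene map
# ---------------------------------------------------------------------------


def load_gene_map(path: str | Path) -> list[GeneRegion]:
    """Read a gene map from delimited text with columns
    name, start, end, strand[, incomplete_terminal]."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise MitoscreenError(f"gene map missing columns: {sorted(missing)}")
    regions = []
    for row in df.itertuples(index=False):
        regions.append(
            GeneRegion(
                name=str(row.name),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                incomplete_terminal=bool(getattr(row, "incomplete_terminal", False)),
            )
        )
    return regions


def default_gene_map() -> list[GeneRegion]:
    """The standard rCRS annotation of the seven mtDNA-encoded complex I genes."""
    return load_gene_map(DATA_DIR / "gene_map.tsv")


def genes_for_position(pos: int, gene_map: Sequence[GeneRegion]) -> list[GeneRegion]:
    """All gene regions whose interval contains ``pos``.

    Overlapping genes (ND4L/ND4) are both returned; an intergenic or
    control-region position yields an empty list.
    """
    if pos < 1:
        raise InvalidCoordinateError(f"position must be >= 1, got {pos}")
    if not gene_map:
        raise MitoscreenError("gene map is empty")
    return [g for g in gene_map if g.contains(pos)]


# ---------------------------------------------------------------------------
# Codon addressing and translation
# ---------------------------------------------------------------------------


def codon_address(pos: int, gene: GeneRegion) -> CodonAddress:
    """Address of ``pos`` in ``gene``'s coding frame.

    For heavy-strand genes the frame is counted upward from ``gene.start``;
    for light-strand genes downward from ``gene.end`` (the coding strand reads
    the reverse complement).  Positions falling in an incomplete terminal
    codon raise :class:`IncompleteCodonError`.
    """
    if not gene.contains(pos):
        raise OutOfGeneError(f"position {pos} outside {gene.name} "
                             f"[{gene.start},{gene.end}]")
    if gene.strand == "heavy":
        offset = pos - gene.start + 1
    else:
        offset = gene.end - pos + 1
    codon_index = math.ceil(offset / 3)
    slot = offset - 3 * (codon_index - 1)
    if codon_index > gene.n_complete_codons:
        raise IncompleteCodonError(
            f"position {pos} lies in the incomplete terminal codon of {gene.name}"
        )
    first_offset = 3 * (codon_index - 1) + 1
    if gene.strand == "heavy":
        p1 = gene.start + first_offset - 1
        triple = (p1, p1 + 1, p1 + 2)
    else:
        p1 = gene.end - first_offset + 1
        triple = (p1, p1 - 1, p1 - 2)
    return CodonAddress(gene.name, codon_index, slot, triple)


def codon_on_coding_strand(
    ref_gene_seq: str, gene: GeneRegion, address: CodonAddress
) -> str:
    """Extract the coding-strand codon named by ``address`` from a
    heavy-strand gene sequence."""
    if len(ref_gene_seq) != gene.length:
        raise MitoscreenError(
            f"{gene.name}: sequence length {len(ref_gene_seq)} != "
            f"interval length {gene.length}"
        )
    lo = min(address.rcrs_positions) - gene.start
    chunk = ref_gene_seq[lo : lo + 3]
    if gene.strand == "light":
        chunk = reverse_complement(chunk)
    return chunk


def translate_codon(codon: str, code: GeneticCode = VERTEBRATE_MITO_CODE) -> str:
    """Translate one unambiguous DNA codon; '*' denotes stop."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise UntranslatableCodonError(f"cannot translate codon {codon!r}")
    return code.codon_to_aa[codon]


def human_aa_change(
    variant,
    ref_gene_seq: str,
    gene: GeneRegion,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> tuple[str, str, bool]:
    """(ref_aa, alt_aa, synonymous) for a variant in the human reference context.

    ``variant`` needs ``position``, ``ref`` and ``alt`` attributes with alleles
    stated on the rCRS heavy strand; for light-strand genes the substitution is
    complemented onto the coding strand before translation.
    """
    ref_base = ref_gene_seq[variant.position - gene.start].upper()
    if ref_base != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{gene.name} m.{variant.position}: reference sequence has "
            f"{ref_base}, variant states {variant.ref}"
        )
    address = codon_address(variant.position, gene)
    ref_codon = codon_on_coding_strand(ref_gene_seq, gene, address)
    if gene.strand == "heavy":
        alt_base = variant.alt.upper()
    else:
        alt_base = complement_base(variant.alt.upper())
    slot = address.within_codon_offset - 1
    alt_codon = ref_codon[:slot] + alt_base + ref_codon[slot + 1 :]
    ref_aa = translate_codon(ref_codon, code)
    alt_aa = translate_codon(alt_codon, code)
    return ref_aa, alt_aa, ref_aa == alt_aa


def next_initiation_codon(
    ref_gene_seq: str,
    gene: GeneRegion,
    after_codon: int = 1,
    start_codons: Iterable[str] = ("ATG", "ATA"),
) -> int | None:
    """Codon index of the first in-frame initiation codon after ``after_codon``.

    Used to locate the alternative initiation site that rescues start-codon
    variants such as m.3308T>C; returns None if no start codon follows.
    """
    starts = {s.upper() for s in start_codons}
    for idx in range(after_codon + 1, gene.n_complete_codons + 1):
        addr = CodonAddress(gene.name, idx, 1, _codon_triple(gene, idx))
        if codon_on_coding_strand(ref_gene_seq, gene, addr) in starts:
            return idx
    return None


def _codon_triple(gene: GeneRegion, codon_index: int) -> tuple[int, int, int]:
    first_offset = 3 * (codon_index - 1) + 1
    if gene.strand == "heavy":
        p1 = gene.start + first_offset - 1
        return (p1, p1 + 1, p1 + 2)
    p1 = gene.end - first_offset + 1
    return (p1, p1 - 1, p1 - 2)
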