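"""Synthetic multi-species gene sets with planted variants and known truth.

Emulates the study's data model — several species, one or more sequences per
species, each gene anchored by an embedded human reference row — under a
star phylogeny: every species ancestor is drawn independently from the root
gene by a two-parameter per-site substitution scheme (probability ``p`` of
substitution, transitions favoured over each transversion by ``kappa``), and
sequences within a species diverge from their ancestor at rate ``q``.  A
chosen alternate allele is planted into all sequences of the carrier
species, optionally together with a within-codon co-variant in a stated
fraction of carriers, and single-base indels can decorate sequences outside
the planted codon.  Everything is replayable from the emitted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .reference_model import GeneRegion, GeneticCode, MitoscreenError, \
    VERTEBRATE_MITO_CODE, codon_address, complement_base, translate_codon
from .sequence_io import (
    ScreenReport,
    SequenceEntry,
    SpeciesSequenceSet,
    VariantRecord,
)

__all__ = [
    "SynthParams",
    "SynthTruth",
    "generate",
    "replay",
    "truth_evaluate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

SYNTHETIC_REFERENCE_ID = "NC_012920_synthetic"


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults are desk-scale study-like conditions.

    ``planted_variant`` is ``(rcrs_position, ref, alt)`` with the position
    inside ``gene``; ``planted_comask`` is ``(within_codon_offset, allele,
    concordance)`` placing a co-variant at another coding slot of the planted
    codon in that fraction of carrier sequences (and never in non-carriers).
    """

    root_gene_seq: str
    gene: GeneRegion
    n_species: int = 10
    seqs_per_species: int = 3
    interspecies_divergence: float = 0.02  # p, per site
    intraspecies_divergence: float = 0.005  # q, per site
    transition_bias: float = 2.0  # kappa
    carrier_species: tuple[str, ...] = ()
    planted_variant: Optional[tuple[int, str, str]] = None
    planted_comask: Optional[tuple[int, str, float]] = None
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.root_gene_seq) != self.gene.length:
            raise MitoscreenError("root sequence length != gene interval length")
        for name in ("interspecies_divergence", "intraspecies_divergence",
                     "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise MitoscreenError(f"{name}={v} outside [0, 1)")
        if self.transition_bias < 0:
            raise MitoscreenError("transition_bias must be >= 0")
        known = set(self.species_names())
        unknown = set(self.carrier_species) - known
        if unknown:
            raise MitoscreenError(f"carrier species not generated: {sorted(unknown)}")
        if self.planted_variant is not None:
            pos, ref, alt = self.planted_variant
            if not self.gene.contains(pos):
                raise MitoscreenError(f"planted position {pos} outside gene")
            root_base = self.root_gene_seq[pos - self.gene.start].upper()
            if root_base != ref.upper():
                raise MitoscreenError(
                    f"planting error: root base {root_base} != stated ref {ref}"
                )
            if alt.upper() == root_base:
                raise MitoscreenError(
                    "planting error: planted allele equals the root base"
                )
        if self.planted_comask is not None:
            if self.planted_variant is None:
                raise MitoscreenError("planted_comask requires planted_variant")
            offset, _, conc = self.planted_comask
            if offset not in (1, 2, 3):
                raise MitoscreenError("comask within_codon_offset must be 1, 2 or 3")
            if not 0.0 <= conc <= 1.0:
                raise MitoscreenError("comask concordance must lie in [0, 1]")

    def species_names(self) -> list[str]:
        return [f"Synthspecies sp{i + 1:02d}" for i in range(self.n_species)]

    def comask_rcrs_position(self) -> Optional[int]:
        if self.planted_comask is None:
            return None
        address = codon_address(self.planted_variant[0], self.gene)
        pos = address.rcrs_positions[self.planted_comask[0] - 1]
        if pos == self.planted_variant[0]:
            raise MitoscreenError(
                "comask offset coincides with the planted variant slot"
            )
        return pos


@dataclass
class SynthTruth:
    """Replayable record of everything the generator did."""

    gene: str
    species_of: dict[str, str]
    carrier_status: dict[str, bool]
    comask_status: dict[str, bool]
    substitutions: dict[str, list[tuple[int, str, str]]]  # (rcrs pos, from, to)
    indels: dict[str, list[tuple[str, int, str]]]  # (op, 0-based index, base)
    tree_newick: str
    planted_variant: Optional[tuple[int, str, str]]
    comask_position: Optional[int]
    comask_allele: Optional[str]

    def carriers(self) -> set[str]:
        return {sid for sid, c in self.carrier_status.items() if c}


def _mutate(seq_codes: np.ndarray, rate: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with transition bias; returns mutated copy."""
    out = seq_codes.copy()
    hit = np.flatnonzero(rng.random(out.size) < rate)
    if hit.size == 0:
        return out
    p_ts = kappa / (kappa + 2.0) if kappa + 2.0 > 0 else 0.0
    u = rng.random(hit.size)
    for idx, pick in zip(hit, u):
        base = chr(out[idx])
        if base not in "ACGT":
            continue
        if pick < p_ts:
            new = _TRANSITION[base]
        else:
            tv = sorted(set("ACGT") - {base, _TRANSITION[base]})
            new = tv[0] if pick < p_ts + (1.0 - p_ts) / 2.0 else tv[1]
        out[idx] = ord(new)
    return out


def generate(params: SynthParams) -> tuple[SpeciesSequenceSet, SynthTruth]:
    """Emit a per-gene sequence set (with embedded reference row) plus truth.

    Deterministic under a fixed seed: same params → byte-identical FASTA.
    """
    rng = np.random.default_rng(params.seed)
    root = params.root_gene_seq.upper()
    root_codes = np.frombuffer(root.encode(), dtype=np.uint8).copy()
    gene = params.gene
    v = params.planted_variant
    comask_pos = params.comask_rcrs_position()
    protected: set[int] = set()
    if v is not None:
        protected = set(codon_address(v[0], gene).rcrs_positions)

    entries = [SequenceEntry(SYNTHETIC_REFERENCE_ID, "Homo sapiens", root)]
    species_of: dict[str, str] = {}
    carrier_status: dict[str, bool] = {}
    comask_status: dict[str, bool] = {}
    substitutions: dict[str, list[tuple[int, str, str]]] = {}
    indels: dict[str, list[tuple[str, int, str]]] = {}

    carrier_seq_ids: list[str] = []
    per_seq_codes: dict[str, np.ndarray] = {}
    for si, species in enumerate(params.species_names()):
        ancestor = _mutate(root_codes, params.interspecies_divergence,
                           params.transition_bias, rng)
        is_carrier_species = species in params.carrier_species
        for k in range(params.seqs_per_species):
            sid = f"syn{si + 1:02d}_{k + 1:02d}"
            codes = _mutate(ancestor, params.intraspecies_divergence,
                            params.transition_bias, rng)
            if v is not None and is_carrier_species:
                codes[v[0] - gene.start] = ord(v[2].upper())
            species_of[sid] = species
            carrier_status[sid] = bool(v is not None and is_carrier_species)
            comask_status[sid] = False
            per_seq_codes[sid] = codes
            if carrier_status[sid]:
                carrier_seq_ids.append(sid)

    if params.planted_comask is not None and carrier_seq_ids:
        _, allele, conc = params.planted_comask
        n_with = math.ceil(conc * len(carrier_seq_ids))
        heavy_allele = (allele.upper() if gene.strand == "heavy"
                        else complement_base(allele.upper()))
        for sid in carrier_seq_ids[:n_with]:
            per_seq_codes[sid][comask_pos - gene.start] = ord(heavy_allele)
            comask_status[sid] = True

    for sid, codes in per_seq_codes.items():
        subs = [
            (int(i) + gene.start, root[i], chr(c))
            for i, c in enumerate(codes)
            if c != root_codes[i]
        ]
        substitutions[sid] = subs
        seq = codes.tobytes().decode()
        ops: list[tuple[str, int, str]] = []
        if params.indel_rate > 0:
            hit = np.flatnonzero(rng.random(len(seq)) < params.indel_rate)
            for i in sorted((int(i) for i in hit), reverse=True):
                if i + gene.start in protected or (comask_pos is not None
                                                   and i + gene.start == comask_pos):
                    continue
                if rng.random() < 0.5:
                    ops.append(("del", i, seq[i]))
                    seq = seq[:i] + seq[i + 1 :]
                else:
                    base = "ACGT"[int(rng.integers(4))]
                    ops.append(("ins", i, base))
                    seq = seq[:i] + base + seq[i:]
        indels[sid] = ops
        entries.append(SequenceEntry(sid, species_of[sid], seq))

    aligned = params.indel_rate == 0.0
    sset = SpeciesSequenceSet(gene.name, entries, aligned=aligned,
                              reference_row_id=SYNTHETIC_REFERENCE_ID)
    tree = "(" + ",".join(
        s.replace(" ", "_") for s in params.species_names()
    ) + ");"
    truth = SynthTruth(
        gene=gene.name,
        species_of=species_of,
        carrier_status=carrier_status,
        comask_status=comask_status,
        substitutions=substitutions,
        indels=indels,
        tree_newick=tree,
        planted_variant=v,
        comask_position=comask_pos,
        comask_allele=(None if params.planted_comask is None
                       else params.planted_comask[1].upper()),
    )
    return sset, truth


def replay(truth: SynthTruth, root_gene_seq: str, gene: GeneRegion,
           sequence_id: str) -> str:
    """Rebuild one emitted sequence from the truth log (invariant check)."""
    seq = list(root_gene_seq.upper())
    for pos, old, new in truth.substitutions[sequence_id]:
        idx = pos - gene.start
        if seq[idx] != old:
            raise MitoscreenError(f"replay mismatch at {pos}")
        seq[idx] = new
    s = "".join(seq)
    for op, i, base in truth.indels[sequence_id]:
        if op == "del":
            s = s[:i] + s[i + 1 :]
        else:
            s = s[:i] + base + s[i:]
    return s


def _expected_masking_class(truth: SynthTruth, root: str, gene: GeneRegion,
                            code: GeneticCode) -> Optional[str]:
    """Independent expectation of the carrier codon-context class, valid for
    noise-free runs with full-concordance comasks."""
    if truth.planted_variant is None:
        return None
    pos, ref, alt = truth.planted_variant
    address = codon_address(pos, gene)
    lo = min(address.rcrs_positions) - gene.start
    heavy = list(root[lo : lo + 3])
    order = sorted(address.rcrs_positions)
    if truth.comask_position is not None:
        heavy_allele = (truth.comask_allele if gene.strand == "heavy"
                        else complement_base(truth.comask_allele))
        heavy[order.index(truth.comask_position)] = heavy_allele
    def coding(codon_heavy: list[str], variant_base: str) -> str:
        c = codon_heavy.copy()
        c[order.index(pos)] = variant_base
        s = "".join(c)
        if gene.strand == "light":
            s = "".join(complement_base(b) for b in reversed(s))
        return s
    aa_ref = translate_codon(coding(heavy, ref), code)
    aa_alt = translate_codon(coding(heavy, alt), code)
    human_ref = translate_codon(coding(list(root[lo : lo + 3]), ref), code)
    human_alt = translate_codon(coding(list(root[lo : lo + 3]), alt), code)
    if truth.comask_position is None:
        return "IDENTICAL"
    if aa_ref == aa_alt:
        return "SYNONYMOUS_IN_CONTEXT"
    return "ALTERED_SUBSTITUTION"


def truth_evaluate(
    report: ScreenReport,
    truth: SynthTruth,
    root_gene_seq: Optional[str] = None,
    gene: Optional[GeneRegion] = None,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> dict[str, float]:
    """Recovery metrics of a screen run against generator truth.

    Carrier-calling sensitivity/specificity are per sequence; masking
    precision/recall compare recovered candidate positions with the planted
    co-variant.  When the root and gene are supplied, the fraction of carrier
    species whose reported codon-context class matches the noise-free
    expectation is added as ``codon_context_accuracy``.
    """
    if truth.planted_variant is None:
        raise MitoscreenError("truth has no planted variant to evaluate")
    pos = truth.planted_variant[0]
    rows = [r for r in report.rows if r.gene == truth.gene and r.position == pos]
    if len(rows) != 1:
        raise MitoscreenError(
            f"report has {len(rows)} rows for the planted variant at {pos}"
        )
    row = rows[0]
    called = set(row.carrier_sequence_ids)
    unknown_ids = called - set(truth.carrier_status)
    if unknown_ids:
        raise MitoscreenError(f"report names unknown sequences: {sorted(unknown_ids)}")
    true_carriers = truth.carriers()
    all_ids = set(truth.carrier_status)
    tp = len(called & true_carriers)
    fn = len(true_carriers - called)
    fp = len(called - true_carriers)
    tn = len(all_ids - true_carriers - called)
    metrics: dict[str, float] = {
        "carrier_sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
        "carrier_specificity": tn / (tn + fp) if (tn + fp) else 1.0,
    }
    predicted = {c["position"] for c in row.masking_candidates}
    expected = (set() if truth.comask_position is None
                else {truth.comask_position})
    hit = len(predicted & expected)
    metrics["masking_precision"] = (hit / len(predicted)) if predicted else \
        (1.0 if not expected else 0.0)
    metrics["masking_recall"] = (hit / len(expected)) if expected else 1.0
    if root_gene_seq is not None and gene is not None and row.resolutions:
        want = _expected_masking_class(truth, root_gene_seq.upper(), gene, code)
        carrier_species = {truth.species_of[sid] for sid in true_carriers}
        judged = [r for r in row.resolutions if r["species"] in carrier_species]
        if judged:
            metrics["codon_context_accuracy"] = sum(
                r["class"] == want for r in judged
            ) / len(judged)
    return metrics
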