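"""Codon-context resolution of variant consequences and masking-variant
screening.

A human substitution that is deleterious in the human codon can land in a
different codon in another lineage: additional within-codon differences may
change, or silence, the amino-acid consequence ("masking").  This module
resolves each variant inside every species' own codon and screens carrier
sequences for alleles perfectly concordant with carrier status — candidate
masking variants in the sense of haplogroup markers travelling with the
pathogenic allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .alignment import HomologyMap
from .cross_species_screen import MISSING, VariantCalls, call_variant, observed_codon
from .reference_model import (
    GeneRegion,
    GeneticCode,
    MitoscreenError,
    VERTEBRATE_MITO_CODE,
    codon_address,
    codon_on_coding_strand,
    complement_base,
    translate_codon,
)
from .sequence_io import SpeciesSequenceSet, VariantRecord

__all__ = [
    "IDENTICAL",
    "ALTERED_SUBSTITUTION",
    "SYNONYMOUS_IN_CONTEXT",
    "UNTRANSLATABLE",
    "UNRESOLVED",
    "CodonResolution",
    "MaskingCandidate",
    "resolve_codon_per_sequence",
    "resolve_codon",
    "screen_masking_candidates",
]

IDENTICAL = "IDENTICAL"
ALTERED_SUBSTITUTION = "ALTERED_SUBSTITUTION"
SYNONYMOUS_IN_CONTEXT = "SYNONYMOUS_IN_CONTEXT"
UNTRANSLATABLE = "UNTRANSLATABLE"
UNRESOLVED = "UNRESOLVED"

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CodonResolution:
    """Effective consequence of a human variant in one species' codon context.

    ``species_aa_with_ref``/``species_aa_with_alt`` translate the species
    codon with the human reference/alternate base forced into the variant
    slot; ``covarying_positions`` are the other codon positions (rCRS
    numbering) where the species differs from the rCRS.  Classes:

    - IDENTICAL: no within-codon co-variation; the species reproduces the
      human amino-acid change exactly.
    - ALTERED_SUBSTITUTION: co-variation changes the resulting substitution
      (e.g. human M→V becoming M→G in fish).
    - SYNONYMOUS_IN_CONTEXT: in this codon background the variant no longer
      changes the amino acid.
    - UNTRANSLATABLE: a codon slot is gapped or ambiguous.

    When a species has several sequences the resolution is the majority codon
    with ``n_discordant`` sequences disagreeing.
    """

    species_label: str
    human_change: tuple[str, str]
    species_codon_observed: str  # 3-mer or UNRESOLVED
    species_aa_with_ref: Optional[str]
    species_aa_with_alt: Optional[str]
    masking_class: str
    covarying_positions: tuple[int, ...]
    n_sequences: int = 1
    n_discordant: int = 0

    def to_record(self) -> dict:
        return {
            "species": self.species_label,
            "human_change": f"{self.human_change[0]}>{self.human_change[1]}",
            "codon": self.species_codon_observed,
            "aa_with_ref": self.species_aa_with_ref,
            "aa_with_alt": self.species_aa_with_alt,
            "class": self.masking_class,
            "covarying_positions": list(self.covarying_positions),
            "n_sequences": self.n_sequences,
            "n_discordant": self.n_discordant,
        }


@dataclass(frozen=True)
class MaskingCandidate:
    """An allele concordant with the carrier partition of a variant."""

    position: int
    allele: str
    carrier_overlap: float
    non_carrier_presence: float
    within_codon: bool

    def to_record(self) -> dict:
        return {
            "position": self.position,
            "allele": self.allele,
            "carrier_overlap": self.carrier_overlap,
            "non_carrier_presence": self.non_carrier_presence,
            "within_codon": self.within_codon,
        }


def _classify(
    codon: Optional[str],
    variant: VariantRecord,
    gene: GeneRegion,
    address,
    ref_gene_seq: str,
    code: GeneticCode,
    human_change: tuple[str, str],
    hmap_bases,
):
    """(codon_observed, aa_ref, aa_alt, class, covarying) for one sequence."""
    if codon is None:
        return UNRESOLVED, None, None, UNTRANSLATABLE, ()
    slot = address.within_codon_offset - 1
    if gene.strand == "heavy":
        ref_b, alt_b = variant.ref, variant.alt
    else:
        ref_b, alt_b = complement_base(variant.ref), complement_base(variant.alt)
    with_ref = codon[:slot] + ref_b + codon[slot + 1 :]
    with_alt = codon[:slot] + alt_b + codon[slot + 1 :]
    aa_ref = translate_codon(with_ref, code)
    aa_alt = translate_codon(with_alt, code)
    covarying = []
    for k, pos in enumerate(address.rcrs_positions):
        if pos == variant.position:
            continue
        rcrs_base = ref_gene_seq[pos - gene.start].upper()
        species_heavy = codon[k] if gene.strand == "heavy" else complement_base(codon[k])
        if species_heavy != rcrs_base:
            covarying.append(pos)
    covarying_t = tuple(sorted(covarying))
    if not covarying_t:
        cls = IDENTICAL
    elif aa_alt == aa_ref:
        cls = SYNONYMOUS_IN_CONTEXT
    else:
        cls = ALTERED_SUBSTITUTION
    return codon, aa_ref, aa_alt, cls, covarying_t


def resolve_codon_per_sequence(
    sset: SpeciesSequenceSet,
    hmap: HomologyMap,
    variant: VariantRecord,
    gene: GeneRegion,
    ref_gene_seq: str,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
    species: Optional[str] = None,
) -> dict[str, CodonResolution]:
    """Per-sequence codon resolutions, optionally restricted to one species."""
    address = codon_address(variant.position, gene)
    human_codon = codon_on_coding_strand(ref_gene_seq, gene, address)
    slot = address.within_codon_offset - 1
    alt_b = (variant.alt if gene.strand == "heavy"
             else complement_base(variant.alt))
    human_change = (
        translate_codon(human_codon, code),
        translate_codon(human_codon[:slot] + alt_b + human_codon[slot + 1 :], code),
    )
    out: dict[str, CodonResolution] = {}
    for entry in sset.non_reference_entries():
        if species is not None and entry.species_label != species:
            continue
        codon = observed_codon(hmap, entry.sequence_id, gene, address)
        obs, aa_ref, aa_alt, cls, covarying = _classify(
            codon, variant, gene, address, ref_gene_seq, code, human_change, hmap
        )
        out[entry.sequence_id] = CodonResolution(
            entry.species_label, human_change, obs, aa_ref, aa_alt, cls, covarying
        )
    return out


def resolve_codon(
    sset: SpeciesSequenceSet,
    hmap: HomologyMap,
    variant: VariantRecord,
    gene: GeneRegion,
    ref_gene_seq: str,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
    species: Optional[str] = None,
) -> CodonResolution:
    """Species-level codon resolution by majority codon across that species'
    sequences, with the discordance count reported.

    Codon ties break to the lexicographically smallest codon for determinism;
    with ``species=None`` the set must contain a single species.
    """
    if species is None:
        labels = sset.species()
        if len(labels) != 1:
            raise MitoscreenError(
                f"species must be named explicitly; set has {labels}"
            )
        species = labels[0]
    per_seq = resolve_codon_per_sequence(
        sset, hmap, variant, gene, ref_gene_seq, code, species
    )
    if not per_seq:
        raise MitoscreenError(f"no sequences for species {species!r}")
    counts = Counter(r.species_codon_observed for r in per_seq.values())
    top = max(counts.values())
    majority_codon = sorted(c for c, n in counts.items() if n == top)[0]
    representative = next(
        r for r in per_seq.values() if r.species_codon_observed == majority_codon
    )
    n = len(per_seq)
    return CodonResolution(
        species_label=species,
        human_change=representative.human_change,
        species_codon_observed=representative.species_codon_observed,
        species_aa_with_ref=representative.species_aa_with_ref,
        species_aa_with_alt=representative.species_aa_with_alt,
        masking_class=representative.masking_class,
        covarying_positions=representative.covarying_positions,
        n_sequences=n,
        n_discordant=n - counts[majority_codon],
    )


def screen_masking_candidates(
    sset: SpeciesSequenceSet,
    hmap: HomologyMap,
    variant: VariantRecord,
    gene: GeneRegion,
    ref_gene_seq: str,
    scope: str = "gene_wide",
    calls: Optional[VariantCalls] = None,
    min_carrier_overlap: float = 1.0,
    max_non_carrier_presence: float = 0.0,
) -> list[MaskingCandidate]:
    """Alleles concordant with the carrier partition of ``variant``.

    The default strict rule reports an allele only if every analysable
    carrier bears it and no analysable non-carrier does; the tolerance
    fractions relax either side.  ``scope`` is ``gene_wide`` (default, to
    catch markers outside the codon, like the 4205/4232 pattern) or
    ``within_codon``.  No carriers → empty list.
    """
    if scope not in ("gene_wide", "within_codon"):
        raise ValueError(f"unknown masking scope {scope!r}")
    if calls is None:
        calls = call_variant(sset, hmap, variant)
    carriers = calls.carrier_sequence_ids
    non_carriers = calls.non_carrier_sequence_ids()
    if not carriers:
        return []
    address = codon_address(variant.position, gene)
    codon_positions = set(address.rcrs_positions)
    if scope == "within_codon":
        positions = sorted(codon_positions - {variant.position})
    else:
        positions = [p for p in range(gene.start, gene.end + 1)
                     if p != variant.position]
    candidates: list[MaskingCandidate] = []
    for pos in positions:
        rcrs_base = ref_gene_seq[pos - gene.start].upper()
        carrier_bases = [hmap.base_at(sid, pos) for sid in carriers]
        carrier_bases = [b for b in carrier_bases if b in _BASES]
        if not carrier_bases:
            continue
        nc_bases = [hmap.base_at(sid, pos) for sid in non_carriers]
        nc_bases = [b for b in nc_bases if b in _BASES]
        for allele in _BASES:
            if allele == rcrs_base:
                continue
            overlap = carrier_bases.count(allele) / len(carrier_bases)
            presence = (nc_bases.count(allele) / len(nc_bases)
                        if nc_bases else 0.0)
            if overlap >= min_carrier_overlap and presence <= max_non_carrier_presence:
                candidates.append(
                    MaskingCandidate(pos, allele, overlap, presence,
                                     within_codon=pos in codon_positions)
                )
    return candidates
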