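"""Presence calling of human disease alleles across species, carrier
fractions and conservation indices.

Every percentage is computed over *analysable* sequences — those with an
unambiguous base at the homologous site — with gapped/ambiguous sequences
counted and reported as missing, never silently dropped from numerators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .alignment import HomologyMap
from .reference_model import (
    GeneRegion,
    GeneticCode,
    MitoscreenError,
    VERTEBRATE_MITO_CODE,
    codon_address,
    codon_on_coding_strand,
    complement_base,
    human_aa_change,
    translate_codon,
)
from .sequence_io import SpeciesSequenceSet, VariantRecord

__all__ = [
    "MISSING",
    "SiteCall",
    "VariantCalls",
    "ConservationSummary",
    "call_variant",
    "observed_codon",
    "conservation_summary",
    "filter_synonymous",
]

MISSING = "MISSING"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SiteCall:
    sequence_id: str
    species_label: str
    observed_base: str  # A|C|G|T|MISSING
    carries_alt: bool
    at_gap: bool


@dataclass(frozen=True)
class VariantCalls:
    """Site calls for one variant over all non-reference sequences."""

    variant: VariantRecord
    calls: tuple[SiteCall, ...]
    species_fractions: Mapping[str, float]  # carriers / analysable, per species

    @property
    def n_carriers(self) -> int:
        return sum(c.carries_alt for c in self.calls)

    @property
    def n_missing(self) -> int:
        return sum(c.observed_base == MISSING for c in self.calls)

    @property
    def n_analysable(self) -> int:
        return len(self.calls) - self.n_missing

    @property
    def carrier_sequence_ids(self) -> list[str]:
        return [c.sequence_id for c in self.calls if c.carries_alt]

    def non_carrier_sequence_ids(self) -> list[str]:
        return [c.sequence_id for c in self.calls
                if not c.carries_alt and c.observed_base != MISSING]


@dataclass(frozen=True)
class ConservationSummary:
    """Site conservation across the non-reference sequences.

    ``nucleotide_ci``: % of analysable sequences whose base equals the rCRS
    base; ``aa_ci``: % of aa-analysable sequences whose own codon (gene frame,
    coding strand) translates to the human reference residue.  Untranslatable
    codons count as missing for the amino-acid index only.
    """

    nucleotide_ci: Optional[float]
    aa_ci: Optional[float]
    n_analysable: int
    n_missing: int
    n_aa_analysable: int
    n_aa_missing: int


def call_variant(
    sset: SpeciesSequenceSet, hmap: HomologyMap, variant: VariantRecord
) -> VariantCalls:
    """One :class:`SiteCall` per non-reference sequence plus per-species
    carrier fractions.

    A sequence carries the alternate allele iff its base at the homologous
    site equals ``variant.alt``; a gap or ambiguity code makes the call
    MISSING and removes the sequence from every denominator.
    """
    if not hmap.gene.contains(variant.position):
        raise MitoscreenError(
            f"{variant.label} outside {hmap.gene.name} homology map"
        )
    calls: list[SiteCall] = []
    per_species: dict[str, list[bool]] = {}
    for entry in sset.non_reference_entries():
        base = hmap.base_at(entry.sequence_id, variant.position)
        at_gap = base is None
        if at_gap or base not in _BASES:
            observed, carries = MISSING, False
        else:
            observed, carries = base, base == variant.alt
        calls.append(SiteCall(entry.sequence_id, entry.species_label,
                              observed, carries, at_gap))
        if observed != MISSING:
            per_species.setdefault(entry.species_label, []).append(carries)
    fractions = {
        sp: sum(flags) / len(flags) for sp, flags in per_species.items()
    }
    return VariantCalls(variant, tuple(calls), fractions)


def observed_codon(
    hmap: HomologyMap,
    sequence_id: str,
    gene: GeneRegion,
    address,
) -> Optional[str]:
    """The sequence's own coding-strand codon at a codon address, or None if
    any slot is gapped/ambiguous."""
    bases = []
    for pos in address.rcrs_positions:
        b = hmap.base_at(sequence_id, pos)
        if b is None or b not in _BASES:
            return None
        bases.append(b)
    codon = "".join(bases)
    if gene.strand == "light":
        codon = "".join(complement_base(b) for b in codon)
    return codon


def conservation_summary(
    sset: SpeciesSequenceSet,
    hmap: HomologyMap,
    variant: VariantRecord,
    gene: GeneRegion,
    ref_gene_seq: str,
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> ConservationSummary:
    """Nucleotide and amino-acid conservation indices at the variant site.

    Any base differing from the rCRS base lowers ``nucleotide_ci`` whether or
    not it equals the alternate allele.
    """
    address = codon_address(variant.position, gene)
    human_ref_aa = translate_codon(
        codon_on_coding_strand(ref_gene_seq, gene, address), code
    )
    n_conserved = n_analysable = n_missing = 0
    n_aa_conserved = n_aa_analysable = n_aa_missing = 0
    for entry in sset.non_reference_entries():
        base = hmap.base_at(entry.sequence_id, variant.position)
        if base is None or base not in _BASES:
            n_missing += 1
        else:
            n_analysable += 1
            if base == variant.ref:
                n_conserved += 1
        codon = observed_codon(hmap, entry.sequence_id, gene, address)
        if codon is None:
            n_aa_missing += 1
        else:
            n_aa_analysable += 1
            if translate_codon(codon, code) == human_ref_aa:
                n_aa_conserved += 1
    return ConservationSummary(
        nucleotide_ci=(100.0 * n_conserved / n_analysable
                       if n_analysable else None),
        aa_ci=(100.0 * n_aa_conserved / n_aa_analysable
               if n_aa_analysable else None),
        n_analysable=n_analysable,
        n_missing=n_missing,
        n_aa_analysable=n_aa_analysable,
        n_aa_missing=n_aa_missing,
    )


def filter_synonymous(
    variants: Sequence[VariantRecord],
    ref_genes: Mapping[str, str],
    gene_map: Sequence[GeneRegion],
    code: GeneticCode = VERTEBRATE_MITO_CODE,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """(retained, excluded): variants that are synonymous in the human
    reference context are set aside before codon-context and rubric stages."""
    by_name = {g.name: g for g in gene_map}
    retained: list[VariantRecord] = []
    excluded: list[VariantRecord] = []
    for v in variants:
        gene = by_name[v.gene]
        _, _, synonymous = human_aa_change(v, ref_genes[v.gene], gene, code)
        (excluded if synonymous else retained).append(v)
    return retained, excluded
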