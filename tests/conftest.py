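"""Shared fixtures: gene map, packaged reference genes, and builders for
hand-made species sequence sets (all generated in memory; nothing binary)."""

from __future__ import annotations

import pytest

from mitoscreen import default_gene_map
from mitoscreen.pipeline import DEFAULT_REFERENCE_FASTA, _load_reference_genes
from mitoscreen.sequence_io import SequenceEntry, SpeciesSequenceSet

REF_ID = "NC_012920_syn"


@pytest.fixture(scope="session")
def gene_map():
    return {g.name: g for g in default_gene_map()}


@pytest.fixture(scope="session")
def ref_genes():
    return _load_reference_genes(DEFAULT_REFERENCE_FASTA)


def mutate(seq: str, gene, changes: dict[int, str]) -> str:
    """Apply heavy-strand base changes keyed by rCRS position."""
    s = list(seq)
    for pos, base in changes.items():
        s[pos - gene.start] = base
    return "".join(s)


def build_set(
    gene_name: str,
    ref_seq: str,
    gene,
    rows: list[tuple[str, str, dict[int, str]]],
    aligned: bool = True,
) -> SpeciesSequenceSet:
    """A sequence set with the reference row plus mutated copies.

    ``rows`` is [(sequence_id, species_label, {rcrs_pos: heavy_base})];
    a base of '-' introduces a gap (set stays aligned).
    """
    entries = [SequenceEntry(REF_ID, "Homo sapiens", ref_seq)]
    for sid, species, changes in rows:
        entries.append(SequenceEntry(sid, species, mutate(ref_seq, gene, changes)))
    return SpeciesSequenceSet(gene_name, entries, aligned=aligned,
                              reference_row_id=REF_ID)


@pytest.fixture()
def pan_set(gene_map, ref_genes):
    """Pan-genus-style ND1 fixture: four carrier sequences bearing both the
    m.3308 alternate and a second linked allele at m.4232, three reference-like
    non-carriers."""
    gene = gene_map["ND1"]
    rows = [
        (f"pan{i}", "Pan troglodytes", {3308: "C", 4232: "C"}) for i in range(4)
    ] + [
        (f"mus{i}", "Mus musculus", {}) for i in range(3)
    ]
    return build_set("ND1", ref_genes["ND1"], gene, rows)


@pytest.fixture()
def fish_nd3_set(gene_map, ref_genes):
    """Silver-carp-style ND3 fixture: carrier codon differs from the human
    TCC at all three bases (observed coding codon CTT, translating L with the
    alternate allele forced in)."""
    gene = gene_map["ND3"]
    rows = [
        ("carp1", "Hypophthalmichthys molitrix",
         {10191: "C", 10192: "T", 10193: "T"}),
        ("herring1", "Clupea harengus", {}),
    ]
    return build_set("ND3", ref_genes["ND3"], gene, rows)


@pytest.fixture()
def fish_nd6_set(gene_map, ref_genes):
    """Eel-style ND6 fixture (light strand): carriers show coding codon GGA —
    the m.14487 alternate plus a second change in the adjacent coding slot —
    so the human M>V becomes M>G."""
    gene = gene_map["ND6"]
    # coding GGA == heavy TCC over rCRS 14485-14487 (rCRS heavy is TAT)
    rows = [
        (f"eel{i}", "Anguilla anguilla", {14487: "C", 14486: "C"})
        for i in range(2)
    ] + [("gallus1", "Gallus gallus", {})]
    return build_set("ND6", ref_genes["ND6"], gene, rows)
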