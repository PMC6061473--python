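"""Codon-context resolution (masking classes) and masking-candidate screening."""

import random

import pytest

from mitoscreen import (
    VariantRecord,
    build_homology_map,
    resolve_codon,
    resolve_codon_per_sequence,
    screen_masking_candidates,
)
from mitoscreen.codon_context import (
    ALTERED_SUBSTITUTION,
    IDENTICAL,
    SYNONYMOUS_IN_CONTEXT,
    UNTRANSLATABLE,
)
from mitoscreen.reference_model import translate_codon

from conftest import build_set


class TestResolveCodon:
    def test_fish_nd6_altered_substitution_m_to_g(self, fish_nd6_set, gene_map,
                                                  ref_genes):
        """The light-strand m.14487 variant reads M>V in the human codon but
        M>G in fish whose codon carries a second coding-slot change."""
        gene = gene_map["ND6"]
        hmap = build_homology_map(fish_nd6_set, gene)
        v = VariantRecord("ND6", 14487, "T", "C")
        res = resolve_codon(fish_nd6_set, hmap, v, gene, ref_genes["ND6"],
                            species="Anguilla anguilla")
        assert res.human_change == ("M", "V")
        assert res.masking_class == ALTERED_SUBSTITUTION
        assert res.species_aa_with_alt == "G"
        assert res.covarying_positions == (14486,)
        assert res.n_sequences == 2 and res.n_discordant == 0

    def test_fish_nd3_altered_substitution_s_to_l(self, fish_nd3_set, gene_map,
                                                  ref_genes):
        """m.10191 is S>P in the human TCC codon; a fish codon differing at
        all three bases yields L with the alternate allele in place."""
        gene = gene_map["ND3"]
        hmap = build_homology_map(fish_nd3_set, gene)
        v = VariantRecord("ND3", 10191, "T", "C")
        res = resolve_codon(fish_nd3_set, hmap, v, gene, ref_genes["ND3"],
                            species="Hypophthalmichthys molitrix")
        assert res.human_change == ("S", "P")
        assert res.masking_class == ALTERED_SUBSTITUTION
        assert res.species_aa_with_alt == "L"
        assert len(res.covarying_positions) == 2  # all three bases differ

    def test_identical_codon_context(self, pan_set, gene_map, ref_genes):
        gene = gene_map["ND1"]
        hmap = build_homology_map(pan_set, gene)
        v = VariantRecord("ND1", 3308, "T", "C")
        res = resolve_codon(pan_set, hmap, v, gene, ref_genes["ND1"],
                            species="Pan troglodytes")
        assert res.masking_class == IDENTICAL
        assert res.covarying_positions == ()
        assert (res.species_aa_with_ref, res.species_aa_with_alt) == ("M", "T")

    def test_synonymous_in_context(self, gene_map, ref_genes):
        # human TCC (S>P under T>C at slot 1); species codon xTC with slot-2/3
        # context CTN makes both ref- and alt-forced codons leucine family:
        # with ref TTA=L? use slots making ref/alt translate identically.
        gene = gene_map["ND3"]
        v = VariantRecord("ND3", 10191, "T", "C")
        # species codon with slots 2,3 = T,A: ref-forced TTA=L, alt-forced CTA=L
        rows = [("s0", "Clupea harengus",
                 {10191: "C", 10192: "T", 10193: "A"})]
        sset = build_set("ND3", ref_genes["ND3"], gene, rows)
        hmap = build_homology_map(sset, gene)
        res = resolve_codon(sset, hmap, v, gene, ref_genes["ND3"],
                            species="Clupea harengus")
        assert translate_codon("TTA") == translate_codon("CTA") == "L"
        assert res.masking_class == SYNONYMOUS_IN_CONTEXT

    def test_gapped_codon_untranslatable(self, gene_map, ref_genes):
        gene = gene_map["ND3"]
        v = VariantRecord("ND3", 10191, "T", "C")
        rows = [("s0", "Clupea harengus", {10192: "-"})]
        sset = build_set("ND3", ref_genes["ND3"], gene, rows)
        hmap = build_homology_map(sset, gene)
        res = resolve_codon(sset, hmap, v, gene, ref_genes["ND3"],
                            species="Clupea harengus")
        assert res.masking_class == UNTRANSLATABLE
        assert res.species_codon_observed == "UNRESOLVED"

    def test_ref_forced_codon_reproduces_observed_when_no_covariation(
            self, pan_set, gene_map, ref_genes):
        gene = gene_map["ND1"]
        hmap = build_homology_map(pan_set, gene)
        v = VariantRecord("ND1", 3308, "T", "C")
        for res in resolve_codon_per_sequence(
                pan_set, hmap, v, gene, ref_genes["ND1"]).values():
            if res.covarying_positions == () and res.masking_class == IDENTICAL:
                # forcing the reference base back reproduces the human codon
                assert res.species_aa_with_ref == res.human_change[0]

    def test_majority_and_discordance_count(self, gene_map, ref_genes):
        gene = gene_map["ND3"]
        v = VariantRecord("ND3", 10191, "T", "C")
        rows = [("a", "Coregonus lavaretus", {10191: "C"}),
                ("b", "Coregonus lavaretus", {10191: "C"}),
                ("c", "Coregonus lavaretus", {10191: "C", 10192: "T"})]
        sset = build_set("ND3", ref_genes["ND3"], gene, rows)
        hmap = build_homology_map(sset, gene)
        res = resolve_codon(sset, hmap, v, gene, ref_genes["ND3"],
                            species="Coregonus lavaretus")
        assert res.species_codon_observed == "CCC"
        assert res.n_sequences == 3 and res.n_discordant == 1


class TestMaskingCandidates:
    def _screen(self, sset, gene, ref_seq, **kw):
        hmap = build_homology_map(sset, gene)
        v = VariantRecord(gene.name, 3308 if gene.name == "ND1" else 10191,
                          "T", "C")
        return screen_masking_candidates(sset, hmap, v, gene, ref_seq, **kw)

    def test_pan_style_marker_recovered_exactly(self, pan_set, gene_map,
                                                ref_genes):
        cands = self._screen(pan_set, gene_map["ND1"], ref_genes["ND1"])
        assert [(c.position, c.allele) for c in cands] == [(4232, "C")]
        c = cands[0]
        assert c.carrier_overlap == 1.0
        assert c.non_carrier_presence == 0.0
        assert c.within_codon is False

    def test_no_carriers_yields_empty(self, gene_map, ref_genes):
        gene = gene_map["ND1"]
        sset = build_set("ND1", ref_genes["ND1"], gene,
                         [("s0", "Mus musculus", {})])
        assert self._screen(sset, gene, ref_genes["ND1"]) == []

    def test_within_codon_scope_and_flag(self, fish_nd6_set, gene_map,
                                         ref_genes):
        gene = gene_map["ND6"]
        hmap = build_homology_map(fish_nd6_set, gene)
        v = VariantRecord("ND6", 14487, "T", "C")
        cands = screen_masking_candidates(
            fish_nd6_set, hmap, v, gene, ref_genes["ND6"], scope="within_codon"
        )
        assert [(c.position, c.allele) for c in cands] == [(14486, "C")]
        assert cands[0].within_codon is True

    def test_empty_when_carriers_match_non_carriers_elsewhere(self, gene_map,
                                                              ref_genes):
        gene = gene_map["ND1"]
        rows = [("a", "Pan troglodytes", {3308: "C"}),
                ("b", "Mus musculus", {})]
        sset = build_set("ND1", ref_genes["ND1"], gene, rows)
        assert self._screen(sset, gene, ref_genes["ND1"]) == []

    def test_invariant_under_sequence_permutation(self, gene_map, ref_genes):
        gene = gene_map["ND1"]
        rows = [("a", "Pan troglodytes", {3308: "C", 4232: "C"}),
                ("b", "Pan troglodytes", {3308: "C", 4232: "C"}),
                ("c", "Mus musculus", {}),
                ("d", "Rattus norvegicus", {3400: "G"})]
        baseline = None
        for seed in (1, 2, 3):
            shuffled = rows[:]
            random.Random(seed).shuffle(shuffled)
            sset = build_set("ND1", ref_genes["ND1"], gene, shuffled)
            cands = self._screen(sset, gene, ref_genes["ND1"])
            if baseline is None:
                baseline = cands
            assert cands == baseline
        assert [(c.position, c.allele) for c in baseline] == [(4232, "C")]

    def test_tolerances_relax_strict_rule(self, gene_map, ref_genes):
        gene = gene_map["ND1"]
        rows = [("a", "Pan troglodytes", {3308: "C", 4232: "C"}),
                ("b", "Pan troglodytes", {3308: "C", 4232: "C"}),
                ("c", "Pan paniscus", {3308: "C"}),  # breaks strict overlap
                ("d", "Mus musculus", {})]
        sset = build_set("ND1", ref_genes["ND1"], gene, rows)
        assert self._screen(sset, gene, ref_genes["ND1"]) == []
        relaxed = self._screen(sset, gene, ref_genes["ND1"],
                               min_carrier_overlap=0.6)
        assert [(c.position, c.allele) for c in relaxed] == [(4232, "C")]
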