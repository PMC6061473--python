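"""Needleman–Wunsch against independent oracles, homology-map lifting,
consensus calling."""

import random

import pytest
from Bio import Align

from mitoscreen import (
    build_homology_map,
    consensus_sequence,
    needleman_wunsch,
)
from mitoscreen.alignment import GAP, ScoringScheme
from mitoscreen.reference_model import GeneRegion, MitoscreenError
from mitoscreen.sequence_io import SequenceEntry, SpeciesSequenceSet

from conftest import build_set

SCHEME = ScoringScheme()


def brute_force_optimum(a: str, b: str, scheme: ScoringScheme = SCHEME) -> int:
    """Exhaustive enumeration of all global alignments (no DP)."""
    def score(x, y):
        if x not in "ACGT" or y not in "ACGT":
            return 0
        return scheme.match if x == y else scheme.mismatch

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            best = rec(i + 1, j + 1) + score(a[i], b[j])
        if i < len(a):
            cand = rec(i + 1, j) + scheme.gap
            best = cand if best is None else max(best, cand)
        if j < len(b):
            cand = rec(i, j + 1) + scheme.gap
            best = cand if best is None else max(best, cand)
        return best

    return rec(0, 0)


class TestNeedlemanWunsch:
    def test_identity_alignment(self):
        aln = needleman_wunsch("ACGT", "ACGT")
        assert aln.ref_row == aln.query_row == "ACGT"
        assert aln.score == 4 * SCHEME.match

    def test_single_deletion(self):
        aln = needleman_wunsch("ACGT", "ACT")
        assert aln.score == 3 * SCHEME.match + SCHEME.gap
        assert aln.query_row.count(GAP) == 1
        assert aln.score == brute_force_optimum("ACGT", "ACT")

    def test_all_mismatch_beats_double_gaps(self):
        aln = needleman_wunsch("AAAA", "TTTT")
        assert aln.score == 4 * SCHEME.mismatch
        assert aln.ref_row == "AAAA" and aln.query_row == "TTTT"

    def test_rows_ungap_to_inputs_and_no_double_gap_columns(self):
        rng = random.Random(7)
        for _ in range(50):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            aln = needleman_wunsch(a, b)
            assert aln.ref_row.replace(GAP, "") == a
            assert aln.query_row.replace(GAP, "") == b
            assert all(not (x == GAP and y == GAP)
                       for x, y in zip(aln.ref_row, aln.query_row))

    def test_matches_enumeration_oracle_small_pairs(self):
        rng = random.Random(11)
        for _ in range(80):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            assert needleman_wunsch(a, b).score == brute_force_optimum(a, b)

    def test_matches_biopython_global_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = SCHEME.match
        aligner.mismatch_score = SCHEME.mismatch
        aligner.open_gap_score = SCHEME.gap
        aligner.extend_gap_score = SCHEME.gap
        rng = random.Random(13)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
            assert needleman_wunsch(a, b).score == aligner.score(a, b)

    def test_deterministic_tie_breaking(self):
        first = needleman_wunsch("ACAC", "CACA")
        for _ in range(5):
            again = needleman_wunsch("ACAC", "CACA")
            assert (again.ref_row, again.query_row) == \
                (first.ref_row, first.query_row)

    def test_ambiguity_scores_zero(self):
        assert needleman_wunsch("NNNN", "ACGT").score == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(MitoscreenError):
            needleman_wunsch("", "ACGT")


def _column_count_oracle(ref_row: str, query_row: str, start: int):
    """Independent per-column gap counting for coordinate lifting."""
    expected = {}
    for col in range(len(ref_row)):
        if ref_row[col] == GAP:
            continue
        pos = start + len(ref_row[: col + 1].replace(GAP, "")) - 1
        if query_row[col] == GAP:
            expected[pos] = None
        else:
            expected[pos] = len(query_row[: col + 1].replace(GAP, ""))
    return expected


class TestHomologyMap:
    def _gene(self, length, start=101):
        pad = (3 - length % 3) % 3
        return GeneRegion("X", start, start + length - 1, "heavy",
                          incomplete_terminal=pad != 0)

    def test_ungapped_aligned_set_is_offset_map(self, gene_map, ref_genes):
        gene = gene_map["ND3"]
        sset = build_set("ND3", ref_genes["ND3"], gene,
                         [("s1", "Mus musculus", {})])
        hmap = build_homology_map(sset, gene)
        for pos in (gene.start, 10191, gene.end):
            assert hmap.column_of(pos) == pos - gene.start + 1
            assert hmap.position_in("s1", pos) == pos - gene.start + 1

    def test_gap_in_reference_row_shifts_columns(self):
        gene = GeneRegion("X", 101, 103, "heavy")
        entries = [SequenceEntry("r", "Homo sapiens", "A-CG"),
                   SequenceEntry("q", "Mus musculus", "ATCG")]
        sset = SpeciesSequenceSet("X", entries, aligned=True,
                                  reference_row_id="r")
        hmap = build_homology_map(sset, gene)
        assert hmap.column_of(102) == 3  # second reference base sits in col 3
        assert hmap.position_in("q", 102) == 3
        assert hmap.base_at("q", 101) == "A"

    def test_random_gapped_fixtures_match_column_counting(self):
        rng = random.Random(17)
        for _ in range(40):
            n = rng.randint(6, 40)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            query = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 40)))
            aln = needleman_wunsch(ref, query)
            gene = self._gene(n)
            entries = [SequenceEntry("r", "Homo sapiens", aln.ref_row),
                       SequenceEntry("q", "Mus musculus", aln.query_row)]
            sset = SpeciesSequenceSet("X", entries, aligned=True,
                                      reference_row_id="r")
            hmap = build_homology_map(sset, gene)
            expected = _column_count_oracle(aln.ref_row, aln.query_row,
                                            gene.start)
            got = {pos: hmap.position_in("q", pos)
                   for pos in range(gene.start, gene.end + 1)}
            assert got == expected

    def test_unaligned_input_anchored_by_pairwise_alignment(self):
        ref = "ACGTACGTACGT"
        gene = self._gene(len(ref))
        query = "ACGTACTACGT"  # one deletion
        entries = [SequenceEntry("q", "Mus musculus", query)]
        sset = SpeciesSequenceSet("X", entries, aligned=False)
        hmap = build_homology_map(sset, gene, ref)
        imgs = [hmap.position_in("q", p) for p in range(gene.start, gene.end + 1)]
        non_gap = [p for p in imgs if p is not None]
        assert non_gap == sorted(set(non_gap))  # strictly monotone
        assert imgs.count(None) == 1

    def test_map_invertible_on_non_gap_image(self, gene_map, ref_genes):
        gene = gene_map["ND3"]
        sset = build_set("ND3", ref_genes["ND3"], gene,
                         [("s1", "Mus musculus", {10191: "-"})])
        hmap = build_homology_map(sset, gene)
        imgs = {}
        for pos in range(gene.start, gene.end + 1):
            q = hmap.position_in("s1", pos)
            if q is not None:
                assert q not in imgs.values()
                imgs[pos] = q
        assert hmap.position_in("s1", 10191) is None

    def test_aligned_input_without_reference_row_errors(self):
        entries = [SequenceEntry("q", "Mus musculus", "ACG")]
        sset = SpeciesSequenceSet("X", entries, aligned=True)
        with pytest.raises(MitoscreenError):
            build_homology_map(sset, GeneRegion("X", 101, 103, "heavy"))


class TestConsensus:
    def _set(self, rows, species="Pan troglodytes"):
        entries = [SequenceEntry(f"s{i}", species, r)
                   for i, r in enumerate(rows)]
        return SpeciesSequenceSet("X", entries, aligned=True)

    def test_single_row_is_identity(self):
        assert consensus_sequence(self._set(["AC-GT"])) == "AC-GT"

    def test_majority_wins(self):
        assert consensus_sequence(self._set(["ACGT", "ACGT", "ACGA"])) == "ACGT"

    def test_identical_rows_for_any_k(self):
        for k in (1, 2, 5):
            assert consensus_sequence(self._set(["ACGT"] * k)) == "ACGT"

    def test_gap_wins_only_when_all_rows_gapped(self):
        assert consensus_sequence(self._set(["A-GT", "A-GT", "ACGT"])) == "ACGT"

    def test_tie_rules(self):
        tied = self._set(["ACGT", "ACGT", "CCGT", "CCGT"])
        assert consensus_sequence(tied, "alphabetical")[0] == "A"
        assert consensus_sequence(tied, "iupac")[0] == "M"

    def test_empty_set_rejected(self):
        with pytest.raises(MitoscreenError):
            consensus_sequence(self._set([]))
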