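"""Pair and combination enrichment statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from ctfbs.coloc_stats import (
    Combination,
    PairTestResult,
    combo_presence,
    enumerate_combinations,
    fisher_one_sided,
    pair_correction_factors,
    pair_presence,
    score_and_select,
    score_matrices,
    test_all_pairs as run_pair_tests,
    test_combinations as run_combination_tests,
)

from conftest import hypergeom_tail_oracle, make_cohort, make_presence


class TestFisherOneSided:
    def test_least_extreme_table_gives_p_one(self):
        assert fisher_one_sided(0, 10, 0, 10) == pytest.approx(1.0)

    def test_known_exact_value_17_over_70(self):
        # margins (4, 4) rows x (4, 4) cols: full enumeration gives 17/70
        expected = Fraction(17, 70)
        assert fisher_one_sided(3, 1, 1, 3) == pytest.approx(float(expected))
        assert hypergeom_tail_oracle(3, 1, 1, 3) == pytest.approx(
            float(expected))

    def test_rejects_empty_class_and_negative_counts(self):
        with pytest.raises(ValueError, match="empty class"):
            fisher_one_sided(0, 0, 1, 1)
        with pytest.raises(ValueError, match=">= 0"):
            fisher_one_sided(-1, 2, 1, 1)

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive agreement with direct hypergeometric summation for
        all tables with total N <= 25 (the full N <= 60 sweep runs in the
        acceptance suite)."""
        for total in range(2, 26):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        if a + b == 0 or c + d == 0:
                            continue
                        assert fisher_one_sided(a, b, c, d) == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), rel=1e-10)

    def test_one_sided_monotonicity_in_a(self):
        """With all margins fixed, moving a success from the background
        row to the positive row strictly decreases p."""
        prev = None
        for a in range(0, 8):
            # margins fixed: rows (10, 10), columns (7, 13)
            p = fisher_one_sided(a, 10 - a, 7 - a, 3 + a)
            if prev is not None:
                assert p < prev
            prev = p


def _pair_fixture():
    """3 genes; g1's first promoter has both motifs, its second has only
    m2; g2 has m1 and m2 split across promoters; g3 has m1 twice."""
    cohort = make_cohort([
        ("g1", True, True, ["A" * 20, "A" * 20]),
        ("g2", False, True, ["A" * 20, "A" * 20]),
        ("g3", False, False, ["A" * 20]),
    ])
    presence = make_presence(cohort, ["m1", "m2"], {
        ("g1_p1", "m1"): [0], ("g1_p1", "m2"): [8],
        ("g1_p2", "m2"): [3],
        ("g2_p1", "m1"): [0], ("g2_p2", "m2"): [5],
        ("g3_p1", "m1"): [0, 7],
    })
    return cohort, presence


class TestPairPresence:
    def test_single_motif_does_not_make_a_heterotypic_pair(self):
        _, presence = _pair_fixture()
        per_gene = pair_presence(presence, "m1", "m2")
        assert per_gene.tolist() == [True, False, False]

    def test_split_across_promoters_is_not_colocalized(self):
        _, presence = _pair_fixture()
        # g2 carries m1 and m2 but never in the same promoter
        assert not pair_presence(presence, "m1", "m2")[1]

    def test_homotypic_needs_two_distinct_positions(self):
        _, presence = _pair_fixture()
        homotypic = pair_presence(presence, "m1", "m1")
        assert homotypic.tolist() == [False, False, True]

    def test_unknown_motif_rejected(self):
        _, presence = _pair_fixture()
        with pytest.raises(KeyError):
            pair_presence(presence, "m1", "nope")


class TestTestAllPairs:
    def test_correction_factors_follow_library_size(self):
        assert pair_correction_factors(522) == (522, 135_981)
        assert pair_correction_factors(3) == (3, 3)

    def test_three_matrix_library_yields_six_tests(self):
        cohort = make_cohort([
            ("g1", True, True, ["A" * 20]),
            ("g2", False, False, ["A" * 20]),
        ])
        presence = make_presence(cohort, ["m1", "m2", "m3"], {})
        results = run_pair_tests(presence, ["g1"], ["g2"])
        assert len(results) == 6
        homo = [r for r in results if r.motif_i == r.motif_j]
        hetero = [r for r in results if r.motif_i != r.motif_j]
        assert len(homo) == 3 and len(hetero) == 3
        assert all(r.correction_factor == 3 for r in results)
        for r in results:
            assert r.corrected_p >= r.raw_p
            assert r.corrected_p <= 1.0
            assert r.a + r.b == 1 and r.c + r.d == 1

    def test_planted_pair_attains_minimum_corrected_p(self):
        genes = [(f"p{i}", False, True, ["A" * 20]) for i in range(5)]
        genes += [(f"b{i}", False, False, ["A" * 20]) for i in range(5)]
        cohort = make_cohort(genes)
        occurrences = {}
        for i in range(5):  # plant m1+m2 in every positive gene
            occurrences[(f"p{i}_p1", "m1")] = [0]
            occurrences[(f"p{i}_p1", "m2")] = [9]
        occurrences[("b0_p1", "m3")] = [0]
        presence = make_presence(cohort, ["m1", "m2", "m3"], occurrences)
        results = run_pair_tests(presence,
                                 [f"p{i}" for i in range(5)],
                                 [f"b{i}" for i in range(5)])
        best = min(results, key=lambda r: r.corrected_p)
        assert (best.motif_i, best.motif_j) == ("m1", "m2")
        assert best.a == 5 and best.c == 0
        # direct arithmetic: raw p = 1/C(10,5), factor (9-3)/2 = 3
        assert best.raw_p == pytest.approx(1 / math.comb(10, 5))
        assert best.corrected_p == pytest.approx(3 / math.comb(10, 5))


class TestScoreAndSelect:
    def _results(self, table):
        return [
            PairTestResult(i, j, 0, 1, 0, 1, p, 1, p)
            for (i, j), p in table.items()
        ]

    def test_hand_summed_scores_and_ordering(self):
        table = {
            ("m1", "m1"): 0.10, ("m1", "m2"): 0.20, ("m1", "m3"): 0.30,
            ("m2", "m2"): 0.40, ("m2", "m3"): 0.50, ("m3", "m3"): 0.60,
        }
        scores = {s.motif_id: s.s_score
                  for s in score_matrices(self._results(table))}
        assert scores["m1"] == pytest.approx(0.10 + 0.20 + 0.30)
        assert scores["m2"] == pytest.approx(0.20 + 0.40 + 0.50)
        assert scores["m3"] == pytest.approx(0.30 + 0.50 + 0.60)
        assert score_and_select(self._results(table), 2) == ["m1", "m2"]

    def test_degenerate_all_ones_breaks_ties_lexicographically(self):
        ids = ["mB", "mA", "mC"]
        table = {(i, j): 1.0
                 for a, i in enumerate(sorted(ids))
                 for j in sorted(ids)[a:]}
        selected = score_and_select(self._results(table), 2)
        assert selected == ["mA", "mB"]

    def test_selection_invariant_to_input_ordering(self):
        table = {
            ("m1", "m1"): 0.9, ("m1", "m2"): 0.1, ("m1", "m3"): 0.8,
            ("m2", "m2"): 0.2, ("m2", "m3"): 0.7, ("m3", "m3"): 0.3,
        }
        results = self._results(table)
        fwd = score_and_select(results, 2)
        rev = score_and_select(list(reversed(results)), 2)
        assert fwd == rev

    def test_top_n_larger_than_library_rejected(self):
        table = {("m1", "m1"): 0.5}
        with pytest.raises(ValueError, match="library"):
            score_and_select(self._results(table), 5)


class TestEnumerateCombinations:
    def test_counts_follow_2_to_n_minus_n_minus_1(self):
        ids10 = [f"m{i:02d}" for i in range(10)]
        combos = enumerate_combinations(ids10)
        assert len(combos) == 1013  # 2^10 - 10 - 1
        assert len(enumerate_combinations(["a", "b"])) == 1

    def test_labels_unique_and_members_sorted_subsets(self):
        ids = ["mC", "mA", "mB", "mD"]
        combos = enumerate_combinations(ids)
        labels = [c.label for c in combos]
        assert len(labels) == len(set(labels)) == 2 ** 4 - 4 - 1
        for c in combos:
            assert list(c.member_ids) == sorted(c.member_ids)
            assert set(c.member_ids) <= set(ids)


def _combo_fixture():
    cohort = make_cohort(
        [(f"p{i}", False, True, ["A" * 20]) for i in range(4)]
        + [(f"c{i}", True, False, ["A" * 20]) for i in range(2)]
        + [(f"b{i}", False, False, ["A" * 20]) for i in range(4)]
    )
    occurrences = {}
    for g in ("p0", "p1", "p2", "c0"):  # plant m1+m2+m3 together
        for m, pos in (("m1", 0), ("m2", 7), ("m3", 14)):
            occurrences[(f"{g}_p1", m)] = [pos]
    occurrences[("b0_p1", "m1")] = [0]
    presence = make_presence(cohort, ["m1", "m2", "m3"], occurrences)
    categories = {g.gene_id: g.category for g in cohort.genes.values()}
    return cohort, presence, categories


class TestComboPresenceAndTests:
    def test_empty_presence_all_false(self):
        cohort = make_cohort([("g1", True, True, ["A" * 20])])
        presence = make_presence(cohort, ["m1", "m2"], {})
        combo = Combination(("m1", "m2"))
        assert not combo_presence(presence, combo).any()

    def test_superset_support_subset_of_subset_support(self):
        _, presence, _ = _combo_fixture()
        small = combo_presence(presence, Combination(("m1", "m2")))
        large = combo_presence(presence, Combination(("m1", "m2", "m3")))
        assert (large <= small).all()

    def test_absent_combination_not_significant(self):
        _, presence, categories = _combo_fixture()
        combos = [Combination(("m2", "m3"))]
        # remove support: test a pair that exists -> use a fresh empty one
        cohort = make_cohort([("g1", False, True, ["A" * 20]),
                              ("g2", False, False, ["A" * 20])])
        empty = make_presence(cohort, ["m2", "m3"], {})
        cats = {g.gene_id: g.category for g in cohort.genes.values()}
        (res,) = run_combination_tests(combos, empty, cats, top_n=3)
        assert res.raw_p == pytest.approx(1.0)
        assert not res.significant

    def test_category_counts_and_holdout_reporting(self):
        _, presence, categories = _combo_fixture()
        combos = [Combination(("m1", "m2", "m3"))]
        (res,) = run_combination_tests(combos, presence, categories,
                                   alpha=0.05, top_n=3)
        # 3 of 4 positives, 1 of 2 held-out C2 genes, 0 of 4 background
        assert res.category_counts["C3"] == 3
        assert res.category_counts["C2"] == 1
        assert res.category_counts["C4"] == 0
        assert res.category_counts["C1+C3"] == \
            res.category_counts["C1"] + res.category_counts["C3"]
        assert res.raw_p == pytest.approx(
            float(hypergeom_tail_oracle(3, 1, 0, 4)))
        assert res.correction_factor == math.comb(3, 3)

    def test_corrected_p_capped_at_one(self):
        _, presence, categories = _combo_fixture()
        results = run_combination_tests(
            enumerate_combinations(["m1", "m2", "m3"]),
            presence, categories, top_n=3)
        for r in results:
            assert r.raw_p <= r.corrected_p <= 1.0
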