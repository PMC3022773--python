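"""Ranking, fold ratios, correlations and interval-overlap statistics."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vlincseq.stats import (
    SampleGroupDesign,
    group_average_correlations,
    interval_overlap,
    max_count_fold_ratio,
    median_length_compare,
    quartile_filter,
    rank_features,
    spearman_matrix,
)
from vlincseq.studies import expression_panel, fold_ratio_panel

from oracles import (
    chi_square_statistic,
    descending_min_ranks,
    interval_membership_counts,
)


class TestRankFeatures:
    def test_tie_handling(self):
        expr = pd.DataFrame({"s": [10, 5, 5, 1]}, index=list("abcd"))
        assert rank_features(expr)["s"].tolist() == [1, 2, 2, 4]

    def test_single_feature(self):
        expr = pd.DataFrame({"s1": [3.0], "s2": [7.0]}, index=["only"])
        assert (rank_features(expr) == 1).all().all()

    def test_missing_values_rank_as_zero(self):
        expr = pd.DataFrame({"s": [10.0, np.nan, 5.0]}, index=list("abc"))
        assert rank_features(expr)["s"].tolist() == [1, 3, 2]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            values = rng.integers(0, 50, size=30).astype(float)
            expr = pd.DataFrame({"s": values})
            assert rank_features(expr)["s"].tolist() == descending_min_ranks(values)


class TestFoldRatio:
    def _design(self):
        return SampleGroupDesign(
            groups={"t1": "tumour", "t2": "tumour", "t3": "tumour",
                    "n1": "normal", "n2": "normal"}
        )

    def test_max_ratio_example(self):
        expr = pd.DataFrame(
            {"t1": [5.0], "t2": [10.0], "t3": [3.0], "n1": [2.0], "n2": [1.0]},
            index=["f"],
        )
        ratios, _ = max_count_fold_ratio(expr, self._design(), pseudocount=0.0)
        assert ratios["f"] == 5.0

    def test_equal_groups_give_unit_median(self):
        expr = pd.DataFrame(
            {s: [4.0, 7.0, 2.0] for s in ("t1", "t2", "t3", "n1", "n2")}
        )
        ratios, summary = max_count_fold_ratio(expr, self._design(), pseudocount=0.0)
        assert (ratios == 1.0).all()
        assert summary.median_ratio == 1.0
        assert np.isnan(summary.p_value)  # zero variance: no evidence either way

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.gamma(3, 10, size=(40, 5)),
            columns=["t1", "t2", "t3", "n1", "n2"],
        )
        r1, _ = max_count_fold_ratio(expr, self._design(), pseudocount=0.0)
        r2, _ = max_count_fold_ratio(expr * 7.3, self._design(), pseudocount=0.0)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy())

    def test_empty_group_fails(self):
        expr = pd.DataFrame({"t1": [1.0]})
        with pytest.raises(ValueError):
            max_count_fold_ratio(expr, SampleGroupDesign(groups={"t1": "tumour"}))

    def test_planted_enrichment_recovered(self):
        """4x planted tumour enrichment on half the features is recovered.

        Equal group sizes cancel the max-of-group bias, so the ratio of the
        enriched-half median to the background-half median estimates the
        planted factor.
        """
        table, design, enriched = fold_ratio_panel(seed=21, enrichment=4.0)
        ratios, summary = max_count_fold_ratio(table, design, pseudocount=0.0)
        med_enriched = float(np.median(ratios[enriched]))
        med_background = float(np.median(ratios[~enriched]))
        assert med_background == pytest.approx(1.0, rel=0.15)
        assert med_enriched / med_background == pytest.approx(4.0, rel=0.2)
        assert summary.p_value < 1e-6
        assert summary.n_tumour_2x >= (enriched.sum() * 0.9)


class TestSpearman:
    def test_duplicated_sample_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        v = rng.gamma(2, 5, 40)
        expr = pd.DataFrame({"a": v, "b": v, "c": rng.gamma(2, 5, 40)})
        corr = spearman_matrix(expr, apply_quartile_filter=False)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "a"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        expr = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [5.0, 4, 3, 2, 1]})
        corr = spearman_matrix(expr, apply_quartile_filter=False)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_manual_rank_computation(self):
        """5-feature table equals rank-then-Pearson computed by hand."""
        expr = pd.DataFrame(
            {"a": [10.0, 7, 7, 2, 1], "b": [9.0, 8, 1, 3, 2], "c": [1.0, 2, 3, 4, 8]}
        )
        corr = spearman_matrix(expr, apply_quartile_filter=False)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            rx = sps.rankdata(expr[x])
            ry = sps.rankdata(expr[y])
            manual = np.corrcoef(rx, ry)[0, 1]
            assert corr.loc[x, y] == pytest.approx(manual)

    def test_constant_vector_reported_missing(self):
        expr = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        corr = spearman_matrix(expr, apply_quartile_filter=False)
        assert np.isnan(corr.loc["a", "b"])

    def test_matrix_symmetric_with_unit_diagonal(self):
        table, _, _ = expression_panel(seed=5, n_features=80)
        corr = spearman_matrix(table)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_quartile_filter_keeps_top_half(self):
        expr = pd.DataFrame(
            {"a": [10.0, 8, 1, 0], "b": [9.0, 7, 2, 0]}, index=list("wxyz")
        )
        kept = quartile_filter(expr)
        assert set(kept.index) == {"w", "x"}

    def test_group_averages_order_on_panel(self):
        """Matched pairs correlate highest; unrelated tumour types lowest."""
        table, design, _ = expression_panel(seed=2)
        avgs = group_average_correlations(spearman_matrix(table), design)
        assert avgs["same_patient"] > avgs["different_patient"]
        assert avgs["different_patient"] > avgs["tumour_vs_other_tumour"]
        assert avgs["same_patient"] > 0.8
        assert abs(avgs["tumour_vs_other_tumour"]) < 0.35


class TestIntervalOverlap:
    def test_identical_sets(self):
        a = [("chr1", 0, 100), ("chr1", 200, 300)]
        universe = [("chr1", 0, 1_000)]
        res = interval_overlap(a, a, universe, min_overlap_bp=1)
        assert res.n_a_overlapping == res.n_b_overlapping == 2
        assert res.bp_overlap == 200

    def test_disjoint_sets(self):
        a = [("chr1", 0, 100)]
        b = [("chr1", 500, 600)]
        res = interval_overlap(a, b, [("chr1", 0, 1_000)])
        assert res.n_a_overlapping == 0
        assert res.bp_overlap == 0

    def test_minimum_overlap_rule(self):
        a = [("chr1", 0, 100)]
        b = [("chr1", 95, 300)]
        assert interval_overlap(a, b, [("chr1", 0, 400)], 5).n_a_overlapping == 1
        assert interval_overlap(a, b, [("chr1", 0, 400)], 6).n_a_overlapping == 0

    def test_negative_min_overlap_fails(self):
        with pytest.raises(ValueError):
            interval_overlap([], [], [], min_overlap_bp=-1)

    def test_contingency_matches_brute_force(self):
        """1 kb universe: per-base membership enumeration agrees exactly."""
        rng = np.random.default_rng(8)
        universe = [("chr1", 0, 1_000)]
        for _ in range(10):
            a = [("chr1", int(s), int(s) + int(rng.integers(10, 200)))
                 for s in rng.integers(0, 800, 3)]
            b = [("chr1", int(s), int(s) + int(rng.integers(10, 200)))
                 for s in rng.integers(0, 800, 3)]
            res = interval_overlap(a, b, universe)
            both, a_only, b_only, neither = interval_membership_counts(a, b, universe)
            assert res.contingency.tolist() == [[both, a_only], [b_only, neither]]
            # bp symmetry
            swapped = interval_overlap(b, a, universe)
            assert res.bp_overlap == swapped.bp_overlap

    def test_chi_square_matches_textbook_formula(self):
        a = [("chr1", 0, 300)]
        b = [("chr1", 200, 600)]
        res = interval_overlap(a, b, [("chr1", 0, 1_000)])
        assert res.chi_square == pytest.approx(
            chi_square_statistic(res.contingency.tolist())
        )
        assert 0 <= res.p_value <= 1


class TestMedianLength:
    def test_identical_sets_similar(self):
        a = [("chr1", 0, 10_000), ("chr1", 0, 20_000), ("chr1", 0, 30_000)]
        res = median_length_compare(a, list(a))
        assert res.median_a == res.median_b == 20_000
        assert res.p_value == pytest.approx(1.0)

    def test_ordering_preserved(self):
        long_set = [("chr1", 0, 50_000 + 10_000 * i) for i in range(10)]
        short_set = [("chr1", 0, 10_000 + 1_000 * i) for i in range(10)]
        res = median_length_compare(long_set, short_set)
        assert res.median_a > res.median_b
        assert res.p_value < 1e-4

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            a = [("chr1", 0, int(x)) for x in rng.integers(1_000, 90_000, 15)]
            b = [("chr1", 0, int(x)) for x in rng.integers(1_000, 90_000, 8)]
            res = median_length_compare(a, b)
            la = sorted(e for _, _, e in a)
            assert res.median_a == float(np.median(la))

    def test_empty_set_fails(self):
        with pytest.raises(ValueError):
            median_length_compare([], [("chr1", 0, 10)])


class TestDesign:
    def test_unknown_group_label_fails(self):
        with pytest.raises(ValueError):
            SampleGroupDesign(groups={"s": "metastasis"})

    def test_pair_classes(self):
        design = SampleGroupDesign(
            groups={"a": "tumour", "b": "tumour", "c": "tumour", "n": "normal"},
            patients={"a": "p1", "b": "p1", "c": "p2", "n": "p9"},
            cohorts={"a": "eft", "b": "eft", "c": "k562", "n": "normal"},
        )
        assert design.pair_class("a", "b") == "same_patient"
        assert design.pair_class("a", "c") == "tumour_vs_other_tumour"
        assert design.pair_class("a", "n") == "tumour_vs_normal"
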