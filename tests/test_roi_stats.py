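"""ROI medians, rank-sum and Spearman tests, and the study comparison grid."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata, spearmanr

from dkihist import (
    CohortSimSpec,
    ROIRecord,
    TissueFractions,
    rank_sum_test,
    roi_median,
    run_study_analyses,
    simulate_cohort,
    spearman_correlation,
)
from dkihist.roi_stats import format_report


def _brute_force_rank_sum_p(x, y):
    """Two-sided permutation p over all C(n1+n2, n1) assignments of the
    pooled midranks; written independently of the implementation."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2.0
    dev_obs = abs(ranks[:n1].sum() - mu)
    total = hits = 0
    for combo in combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestROIMedian:
    def test_odd_count(self):
        assert roi_median(np.array([1.0, 2.0, 3.0]), np.ones(3, bool)) == 2.0

    def test_even_count_averages_central_pair(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0])
        assert roi_median(vals, np.ones(4, bool)) == 2.5

    def test_missing_values_excluded(self):
        vals = np.array([2.0, np.nan, 4.0])
        assert roi_median(vals, np.ones(3, bool)) == 3.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            roi_median(np.full(3, np.nan), np.ones(3, bool))
        with pytest.raises(ValueError):
            roi_median(np.ones(3), np.zeros(3, bool))


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        res = rank_sum_test([1.0, 2.0], [1.0, 2.0])
        assert res.method == "exact"
        assert res.p_value == 1.0

    def test_extreme_small_sample(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.p_value == pytest.approx(1.0 / 3.0)

    def test_smallest_attainable_p_at_n3(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.p_value == pytest.approx(2.0 / math.comb(6, 3))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n1=st.integers(1, 5),
        n2=st.integers(1, 5),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    def test_exact_p_matches_brute_force_enumeration(self, n1, n2, seed, ties):
        rng = np.random.default_rng(seed)
        if ties:
            x = rng.integers(0, 3, n1).astype(float)
            y = rng.integers(0, 3, n2).astype(float)
        else:
            vals = rng.permutation(n1 + n2).astype(float)
            x, y = vals[:n1], vals[n1:]
        res = rank_sum_test(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_brute_force_rank_sum_p(x, y))

    def test_tie_free_exact_matches_mann_whitney(self):
        # cross-check against the scipy exact Mann-Whitney distribution
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            res = rank_sum_test(x, y)
            ref = mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_large_sample_matches_corrected_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 25)
        y = rng.normal(0.6, 1.0, 30)
        res = rank_sum_test(x, y)
        assert res.method == "normal_approx"
        ref = mannwhitneyu(
            x, y, method="asymptotic", use_continuity=True,
            alternative="two-sided",
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=5)
        assert rank_sum_test(x, y).p_value == pytest.approx(
            rank_sum_test(y, x).p_value
        )


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        res = spearman_correlation([1, 2, 3, 5], [2, 8, 9, 50])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_monotone_decreasing_is_minus_one(self):
        res = spearman_correlation([1, 2, 3, 5], [50, 9, 8, 2])
        assert res.statistic == pytest.approx(-1.0)

    def test_midrank_hand_example(self):
        res = spearman_correlation([1, 2, 3, 4], [1, 1, 3, 4])
        assert res.statistic == pytest.approx(4.5 / math.sqrt(22.5))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, 20).astype(float)
        y = rng.integers(0, 5, 20).astype(float) + 0.3 * x
        res = spearman_correlation(x, y)
        ref = spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform_and_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + x
        rho = spearman_correlation(x, y).statistic
        assert spearman_correlation(np.exp(x), y).statistic == pytest.approx(rho)
        assert spearman_correlation(x, y**3).statistic == pytest.approx(rho)
        assert spearman_correlation(x, -y).statistic == pytest.approx(-rho)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])


def _toy_table(n_pairs=6):
    rows = []
    for i in range(n_pairs):
        gs = "low" if i % 2 else "high"
        rows.append(
            dict(patient_id=f"P{i}", roi_id=f"P{i}-T", tissue="tumor",
                 gs_group=gs, median_d_app=1.5 + 0.01 * i,
                 median_k_app=0.7 + 0.05 * i, cellularity=0.30 + 0.05 * i,
                 fsm=0.55 - 0.03 * i, luminal=0.15 - 0.02 * i,
                 area_mm2=50.0)
        )
        rows.append(
            dict(patient_id=f"P{i}", roi_id=f"P{i}-N", tissue="normal",
                 gs_group="none", median_d_app=1.5 + 0.01 * i,
                 median_k_app=0.7 + 0.05 * i, cellularity=0.30 + 0.05 * i,
                 fsm=0.55 - 0.03 * i, luminal=0.15 - 0.02 * i,
                 area_mm2=50.0)
        )
    import pandas as pd

    return pd.DataFrame(rows)


class TestStudyAnalyses:
    def test_grid_has_22_rows(self):
        results = run_study_analyses(_toy_table())
        assert len(results) == 22
        assert (results.comparison == "tumor_vs_normal").sum() == 5
        assert (results.comparison == "gs_high_vs_low").sum() == 5
        assert (results.comparison == "spearman").sum() == 12

    def test_identical_groups_give_unit_p(self):
        results = run_study_analyses(_toy_table())
        tn = results[results.comparison == "tumor_vs_normal"]
        assert (tn.p_value == 1.0).all()

    def test_perfect_monotone_association_gives_rho_one(self):
        results = run_study_analyses(_toy_table())
        cell = results[
            (results.comparison == "spearman")
            & (results.variable == "median_k_app~cellularity")
            & (results.stratum == "tumor")
        ]
        assert cell.statistic.iloc[0] == pytest.approx(1.0)

    def test_missing_column_named_in_error(self):
        df = _toy_table().drop(columns=["luminal"])
        with pytest.raises(KeyError, match="luminal"):
            run_study_analyses(df)

    def test_simulated_cohort_recovers_calibrated_directions(self):
        table = simulate_cohort(CohortSimSpec(seed=12345))
        results = run_study_analyses(table)
        spearman = results[results.comparison == "spearman"].set_index(
            ["variable", "stratum"]
        )
        k_cell = spearman.loc[("median_k_app~cellularity", "tumor")]
        d_lum = spearman.loc[("median_d_app~luminal", "normal")]
        assert k_cell.statistic > 0 and k_cell.p_value < 0.05
        assert d_lum.statistic > 0 and d_lum.p_value < 0.05

    def test_report_flags_significance(self):
        text = format_report(run_study_analyses(_toy_table()))
        assert "ROI-level" in text
        assert "p < 0.05" in text


class TestROIRecordValidation:
    def test_normal_requires_no_gs_group(self):
        with pytest.raises(ValueError):
            ROIRecord("P1", "P1-N", "normal", "low", 2.0, 0.6,
                      TissueFractions(0.2, 0.6, 0.2), 50.0)

    def test_tumor_requires_gs_group(self):
        with pytest.raises(ValueError):
            ROIRecord("P1", "P1-T", "tumor", "none", 1.5, 0.8,
                      TissueFractions(0.4, 0.5, 0.1), 50.0)
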