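"""Association statistics against independent oracles and closed-form
identities: enumeration for the rank-sum and Fisher tests, the
H = z^2 identity, trend recovery, logistic edge cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from insmeth import loci
from insmeth.association_stats import (age_trend, correlation_matrix,
                                       fisher_exact_2x2, format_p,
                                       kruskal_wallis_by_genotype,
                                       logistic_adjusted,
                                       wilcoxon_case_control)
from insmeth.errors import ConfigError, DegenerateDataError

from oracles import fisher_exact_p, rank_sum_exact_p


class TestWilcoxon:
    def test_small_sample_exact_value(self):
        # all 6 rank splits of {1,2} vs {3,4}: the observed split is one
        # of the two most extreme, so two-sided p = 2/6
        res = wilcoxon_case_control([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)
        assert res.extras["method"] == "exact"

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration(self, seed):
        """For untied samples with n1 + n2 <= 10 the returned p equals
        full enumeration of rank assignments."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6, 2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        a, b = pooled[:n1], pooled[n1:]
        res = wilcoxon_case_control(a, b)
        assert res.extras["method"] == "exact"
        assert res.p_value == pytest.approx(rank_sum_exact_p(a, b))

    def test_identical_samples_null(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        res = wilcoxon_case_control(x, x)
        assert res.p_value > 0.99

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = wilcoxon_case_control([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateDataError, match="empty"):
            wilcoxon_case_control([], [1.0])

    def test_calibrated_t1d_cpg135_below_display_floor(self, t1d_cohort):
        """At the shipped T1D calibration (52±9 vs 68±5, n=485/317) the
        CpG -135 rank-sum p lands far below the 2.2e-16 display floor."""
        case = t1d_cohort.loc[t1d_cohort.group == "T1D", "meth_m135"]
        ctrl = t1d_cohort.loc[t1d_cohort.group == "control", "meth_m135"]
        res = wilcoxon_case_control(case, ctrl)
        assert res.p_value < 2e-16
        assert res.p_display == "<2.2e-16"
        assert res.direction == -1


class TestKruskalWallis:
    def test_two_group_identity_with_ranksum_z(self):
        """With 2 groups, H equals z^2 of the tie-corrected normal
        approximation without continuity correction, so the chi-square
        and normal p-values coincide."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = np.round(rng.normal(50, 5, 25), 0)  # induce ties
            b = np.round(rng.normal(52, 5, 30), 0)
            kw = kruskal_wallis_by_genotype(
                np.concatenate([a, b]),
                np.concatenate([np.zeros(25), np.ones(30)]))
            mw = wilcoxon_case_control(a, b)
            assert kw.p_value == pytest.approx(mw.p_value, abs=1e-9)

    def test_all_tied_gives_h_zero_p_one(self):
        res = kruskal_wallis_by_genotype([3.0] * 9, [0, 1, 2] * 3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateDataError, match="2 genotype groups"):
            kruskal_wallis_by_genotype([1.0, 2.0], [0, 0])

    def test_detects_shipped_asm_effect(self, t1d_cohort):
        """rs689 drives CpG -180 methylation in the calibration; CpG
        -135 has no direct effect and only weak coupling."""
        cases = t1d_cohort[t1d_cohort.group == "T1D"]
        hit = kruskal_wallis_by_genotype(cases["meth_m180"],
                                         cases["geno_rs689"])
        null = kruskal_wallis_by_genotype(cases["meth_m135"],
                                          cases["geno_rs689"])
        assert hit.p_value < 1e-6
        assert null.p_value > 1e-4


class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        corr = correlation_matrix(df)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        corr = correlation_matrix(df)
        assert abs(corr.r.loc["a", "b"]) < 0.1

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        corr = correlation_matrix(df)
        assert np.isnan(corr.r.loc["a", "b"])
        assert ("a", "b") in corr.undefined

    def test_symmetric_unit_diagonal_psd_on_complete_cases(self, t1d_cohort,
                                                           meth_columns):
        cases = t1d_cohort[t1d_cohort.group == "T1D"]
        corr = correlation_matrix(cases[meth_columns])
        r = corr.r.to_numpy()
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.linalg.eigvalsh(r).min() > -1e-10

    def test_too_few_pairs_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(DegenerateDataError, match="complete pairs"):
            correlation_matrix(df)

    def test_spearman_option(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": np.exp(x)})  # monotone, nonlinear
        corr = correlation_matrix(df, method="spearman")
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_adjusted_r2_auxiliary(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(size=100)})
        corr = correlation_matrix(df)
        r2adj = corr.adjusted_r2().loc["a", "b"]
        r2 = corr.r.loc["a", "b"] ** 2
        assert r2adj == pytest.approx(1 - (1 - r2) * 99 / 98)


class TestAgeTrend:
    def test_configured_slope_recovered(self):
        rng = np.random.default_rng(6)
        n = 2000
        ages = rng.uniform(20, 80, n)
        vals = 60.0 - 0.2 * ages + rng.normal(0, 6, n)
        res = age_trend(vals, ages)
        se = res.extras["stderr"]
        assert abs(res.statistic - (-0.2)) < 3 * se

    def test_null_slope(self):
        rng = np.random.default_rng(7)
        res = age_trend(rng.normal(60, 5, 500), rng.uniform(1, 30, 500))
        assert abs(res.statistic) < 0.2

    def test_two_points_rejected(self):
        with pytest.raises(DegenerateDataError, match="n >= 3"):
            age_trend([1.0, 2.0], [10.0, 20.0])

    def test_constant_age_rejected(self):
        with pytest.raises(DegenerateDataError, match="constant age"):
            age_trend([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])


class TestLogistic:
    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(8)
        n = 2000
        labels = np.where(rng.random(n) < 0.5, "case", "control")
        res = logistic_adjusted(labels, rng.normal(60, 6, n),
                                rng.uniform(1, 30, n), case_label="case")
        assert abs(res.extras["log_or"]) < 3 * res.extras["se"]

    def test_perfect_separation_raises(self):
        labels = ["case"] * 10 + ["control"] * 10
        meth = list(np.linspace(40, 49, 10)) + list(np.linspace(51, 60, 10))
        ages = list(np.tile([10.0, 12.0], 10))
        with pytest.raises(DegenerateDataError, match="separation"):
            logistic_adjusted(labels, meth, ages, case_label="case")

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError, match="2 classes"):
            logistic_adjusted(["case"] * 5, np.arange(5.0), np.arange(5.0))

    def test_protective_direction_at_calibrated_cpg135(self, t1d_cohort):
        """Cases sit ~16 points below controls at CpG -135, so higher
        methylation must be protective (OR < 1 per percent)."""
        res = logistic_adjusted(t1d_cohort["group"], t1d_cohort["meth_m135"],
                                t1d_cohort["age"], case_label="T1D")
        assert res.statistic < 1.0
        assert res.direction == -1


class TestFisher:
    def test_exchangeable_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_margin_enumeration(self, seed):
        """For n <= 40 the p-value equals brute-force rational
        enumeration over all tables with the observed margins."""
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
                break
        res = fisher_exact_2x2(t)
        assert res.p_value == pytest.approx(fisher_exact_p(t), rel=1e-9)

    def test_invariant_under_transposition_and_swaps(self):
        t = np.array([[12, 5], [3, 20]])
        p = fisher_exact_2x2(t).p_value
        assert fisher_exact_2x2(t.T).p_value == pytest.approx(p)
        assert fisher_exact_2x2(t[::-1]).p_value == pytest.approx(p)
        assert fisher_exact_2x2(t[:, ::-1]).p_value == pytest.approx(p)

    def test_triple_pattern_contrast_below_floor(self):
        res = fisher_exact_2x2([[70, 415], [0, 317]])
        assert res.p_value <= 2e-16
        assert np.isfinite(res.statistic)  # Haldane-Anscombe OR

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError, match="negative"):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError, match="margin"):
            fisher_exact_2x2([[0, 0], [5, 5]])


class TestPValueConventions:
    def test_display_floor(self):
        assert format_p(1e-20) == "<2.2e-16"
        assert format_p(0.049) == "0.049"

    def test_two_sided_at_least_one_sided(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        two = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        one = stats.mannwhitneyu(a, b, alternative="less",
                                 method="asymptotic", use_continuity=False)
        res = wilcoxon_case_control(a, b)
        assert res.p_value == pytest.approx(two.pvalue)
        assert res.p_value >= min(one.pvalue, 1 - one.pvalue) - 1e-12

    @pytest.mark.parametrize("fn,args", [
        (wilcoxon_case_control, ([1.0, 2, 8], [3.0, 9, 4])),
        (kruskal_wallis_by_genotype, ([1.0, 2, 8, 3, 9, 4], [0, 0, 1, 1, 2, 2])),
        (fisher_exact_2x2, ([[3, 4], [5, 2]],)),
    ])
    def test_p_in_unit_interval(self, fn, args):
        p = fn(*args).p_value
        assert 0 < p <= 1
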