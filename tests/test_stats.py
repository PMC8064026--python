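import numpy as np
import pandas as pd
import pytest

from handeye import (
    GroupStudy,
    correlate,
    independent_t,
    jzs_bf,
    mann_whitney,
    normality_gate,
    summary_t_test,
    winsorize_3sd,
)
from handeye.exceptions import StatsError
from oracles import brute_jzs_bf, brute_mannwhitney_exact_p


class TestWinsorize:
    def test_no_outliers_unchanged(self, rng):
        x = rng.normal(10, 1, size=30)
        np.testing.assert_array_equal(winsorize_3sd(x), x)

    def test_single_high_outlier_spec_arithmetic(self):
        # twenty 10s and one 60: mean 12.38, SD 10.91, threshold ~45.1
        x = np.array([10.0] * 20 + [60.0])
        out = winsorize_3sd(x)
        assert out[-1] == pytest.approx(10.1)
        np.testing.assert_array_equal(out[:-1], x[:-1])

    def test_two_high_outliers_share_replacement(self):
        x = np.array([10.0] * 40 + [500.0, 600.0])
        out = winsorize_3sd(x)
        # both outliers replaced by 1.01 x the largest non-outlier
        assert out[-1] == out[-2] == pytest.approx(1.01 * 10.0)

    def test_low_outlier_scaled_down(self):
        x = np.array([10.0] * 40 + [-500.0])
        out = winsorize_3sd(x)
        assert out[-1] == pytest.approx(0.99 * 10.0)

    def test_identical_values_returned_unchanged(self):
        x = np.full(10, 3.0)
        np.testing.assert_array_equal(winsorize_3sd(x), x)

    def test_output_within_one_percent_of_input_range(self, rng):
        for _ in range(50):
            x = rng.standard_t(df=2, size=40) * 10
            out = winsorize_3sd(x)
            assert out.max() <= 1.01 * x.max() + 1e-12
            assert out.min() >= x.min() - 0.01 * abs(x.min()) - 1e-12

    def test_too_few_values_rejected(self):
        with pytest.raises(StatsError):
            winsorize_3sd([1.0, 2.0])


class TestSummaryT:
    def test_table_of_printed_group_stats_mabc(self):
        res = summary_t_test(3.4, 1.5, 19, 10.3, 2.4, 39)
        assert abs(res.statistic) == pytest.approx(11.4, abs=0.1)
        assert res.df == 56
        assert res.effect_size == pytest.approx(3.2, abs=0.05)
        assert res.p_value < 0.001

    def test_table_of_printed_group_stats_dcdq(self):
        res = summary_t_test(33.3, 13.9, 19, 58.8, 12.5, 39)
        assert abs(res.statistic) == pytest.approx(7.0, abs=0.05)

    def test_identical_stats_give_zero(self):
        res = summary_t_test(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(StatsError):
            summary_t_test(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(StatsError):
            summary_t_test(1.0, 0.0, 5, 2.0, 0.0, 10)


class TestIndependentT:
    def test_identical_groups_zero(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_hand_computable_example(self):
        res = independent_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.674, abs=0.001)
        assert res.df == 4

    def test_consistent_with_summary_form(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1.2, 20)
        raw = independent_t(a, b)
        summ = summary_t_test(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert raw.statistic == pytest.approx(summ.statistic)
        assert raw.p_value == pytest.approx(summ.p_value)
        assert raw.bf10 == pytest.approx(summ.bf10)


class TestJZSBayesFactor:
    def test_null_t_favours_null(self):
        assert jzs_bf(0.0, 20, 20) < 1.0

    def test_strictly_increasing_in_t(self):
        values = [jzs_bf(t, 19, 39) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b > a for a, b in zip(values[:-1], values[1:]))

    @pytest.mark.parametrize("t, n1, n2", [(0.73, 19, 39), (2.54, 19, 39), (11.4, 19, 39), (0.0, 20, 20)])
    def test_matches_dense_trapezoid_oracle(self, t, n1, n2):
        got = jzs_bf(t, n1, n2)
        ref = brute_jzs_bf(t, n1, n2)
        assert got == pytest.approx(ref, rel=1e-4)

    @pytest.mark.parametrize("t, n1, n2", [(0.96, 19, 39), (2.0, 30, 30), (3.5, 12, 40)])
    def test_cross_checks_against_pingouin(self, t, n1, n2):
        from pingouin import bayesfactor_ttest

        ref = float(bayesfactor_ttest(t, n1, n2, paired=False, r=np.sqrt(2) / 2))
        assert jzs_bf(t, n1, n2) == pytest.approx(ref, rel=1e-4)

    def test_paper_scale_conventions(self):
        """A strong group separation gives decisive evidence; a null-ish
        t at the same n supports the null by the 1/3 convention."""
        assert jzs_bf(11.4, 19, 39) > 3
        assert jzs_bf(0.2, 19, 39) < 1 / 3


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert abs(res.effect_size) == 1.0

    def test_identical_distributions_zero_effect(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.effect_size == 0.0

    def test_exact_p_matches_permutation_enumeration(self, rng):
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            res = mann_whitney(a, b)
            ref = brute_mannwhitney_exact_p(a, b)
            assert res.p_value == pytest.approx(ref, abs=1e-10)

    def test_rank_biserial_formula(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15)
        res = mann_whitney(a, b)
        u = res.statistic
        assert res.effect_size == pytest.approx(1 - 2 * u / (12 * 15))

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, bf = correlate(x, 2 * x + 1, "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing_spearman(self, rng):
        x = rng.normal(size=20)
        y = -np.exp(x)  # strictly decreasing in x
        r, p, bf = correlate(x, y, "spearman")
        assert r == pytest.approx(-1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, _, _ = correlate(x, y, "pearson")
        ref = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            correlate(np.ones(10), np.arange(10.0))

    def test_bf_increases_with_strength(self, rng):
        x = rng.normal(size=40)
        weak = correlate(x, x + rng.normal(0, 10, 40), "pearson")[2]
        strong = correlate(x, x + rng.normal(0, 0.3, 40), "pearson")[2]
        assert strong > weak


class TestNormalityGate:
    def test_gaussian_sample_goes_parametric(self, rng):
        assert normality_gate(rng.normal(size=100)) == "student_t"

    def test_skewed_sample_goes_nonparametric(self, rng):
        # exponential at n = 58 is essentially always detected
        assert normality_gate(rng.exponential(size=58)) == "mann_whitney"

    def test_degenerate_input_falls_back(self):
        assert normality_gate(np.ones(20)) == "mann_whitney"
        assert normality_gate([1.0, 2.0]) == "mann_whitney"


class TestGroupStudy:
    @staticmethod
    def make_table(rng, effect=0.0):
        n1, n2 = 19, 39
        rows = []
        for i in range(n1 + n2 + 5):
            group = "DCD" if i < n1 else ("Control" if i < n1 + n2 else "Intermediate")
            rows.append(
                {
                    "participant": f"P{i:03d}",
                    "group": group,
                    "median_lag_s": rng.normal(
                        0.05 + (effect if group == "DCD" else 0.0), 0.05
                    ),
                    "mabc2_standard_score": rng.normal(
                        4 if group == "DCD" else 10, 2
                    ),
                }
            )
        return pd.DataFrame(rows)

    def test_fit_produces_comparison_and_correlations(self, rng):
        table = self.make_table(rng)
        res = GroupStudy(
            table, outcomes=["median_lag_s"], traits=["mabc2_standard_score"]
        ).fit()
        comp = res.comparisons["median_lag_s"]
        assert comp.test in ("student_t", "mann_whitney")
        assert 0 <= comp.p_value <= 1
        assert len(res.correlations) == 1
        # intermediates participate in correlations, not group tests
        assert res.correlations.iloc[0]["n"] == len(table)

    def test_strong_effect_detected(self, rng):
        table = self.make_table(rng, effect=0.15)  # d = 3
        res = GroupStudy(table, outcomes=["median_lag_s"]).fit(gate="student_t")
        comp = res.comparisons["median_lag_s"]
        assert comp.p_value < 0.001
        assert comp.bf10 > 3

    def test_winsorization_tames_outlier(self, rng):
        table = self.make_table(rng)
        table.loc[0, "median_lag_s"] = 5.0  # wildly outlying lag
        res = GroupStudy(table, outcomes=["median_lag_s"]).fit()
        assert res.data["median_lag_s"].max() < 1.0

    def test_summary_is_text(self, rng):
        res = GroupStudy(self.make_table(rng), outcomes=["median_lag_s"]).fit()
        assert "DCD vs Control" in res.summary()

    def test_missing_column_rejected(self, rng):
        with pytest.raises(StatsError):
            GroupStudy(self.make_table(rng), outcomes=["nope"])
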