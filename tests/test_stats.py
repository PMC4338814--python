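import numpy as np
import pandas as pd
import pytest

from oracles import (
    chi2_formula,
    levene_formula,
    mixed_anova_ss,
    monte_carlo_paired_power,
    paired_t_formula,
    rank_sum_exact,
    signed_rank_exact,
    welch_formula,
)
from sacmod import stats as sx


def latency_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "task",
                                       "latency_ms", "valid"])


class TestTaskMeans:
    def frame(self):
        return latency_frame([
            ("s1", "patient", "color", 200.0, True),
            ("s1", "patient", "color", 220.0, True),
            ("s1", "patient", "landolt", 190.0, True),
            ("s1", "patient", "landolt", 150.0, False),  # excluded
            ("s2", "patient", "color", 248.0, True),
            ("s2", "patient", "landolt", 232.0, True),
        ])

    def test_means_use_valid_trials_only(self):
        out = sx.task_means(self.frame())
        assert out.loc["s1", "sl_color"] == 210.0
        assert out.loc["s1", "sl_landolt"] == 190.0

    def test_sld_identity(self):
        out = sx.task_means(self.frame())
        assert out.loc["s2", "sld"] == 248.0 - 232.0 == 16.0

    def test_order_invariance(self):
        f = self.frame()
        shuffled = f.sample(frac=1.0, random_state=4)
        pd.testing.assert_frame_equal(sx.task_means(f), sx.task_means(shuffled))

    def test_subject_missing_a_task_excluded_with_warning(self):
        f = pd.concat([self.frame(), latency_frame(
            [("s3", "control", "color", 260.0, True)])])
        with pytest.warns(UserWarning, match="missing a task"):
            out = sx.task_means(f)
        assert "s3" not in out.index


class TestPercentReduction:
    @pytest.mark.parametrize("color, landolt, expected", [
        (248.0, 232.0, 6.5), (221.0, 178.0, 19.5), (269.0, 209.0, 22.3),
    ])
    def test_group_level_reductions(self, color, landolt, expected):
        assert round(sx.percent_reduction(color, landolt), 1) == expected

    def test_equal_means_zero(self):
        assert sx.percent_reduction(200.0, 200.0) == 0.0

    def test_rejects_nonpositive_color_mean(self):
        with pytest.raises(ValueError):
            sx.percent_reduction(0.0, 100.0)


class TestPairedT:
    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(250, 50, 13), rng.normal(230, 50, 13)
        assert sx.paired_t(a, b).df == 12

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(250, 50, 9), rng.normal(230, 50, 9)
        res = sx.paired_t(a, b)
        t, df, p = paired_t_formula(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_identical_samples_rejected(self):
        a = np.arange(5.0)
        with pytest.raises(ValueError):
            sx.paired_t(a, a)

    def test_one_tailed_halves_two_tailed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(250, 50, 10), rng.normal(200, 50, 10)
        assert sx.paired_t(a, b, tails=1).p_value == pytest.approx(
            sx.paired_t(a, b, tails=2).p_value / 2)


class TestWelchT:
    def test_collapses_to_student_df_for_equal_var_and_n(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0  # identical sample variance
        res = sx.welch_t(a, b)
        assert res.df == pytest.approx(len(a) + len(b) - 2)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(60, 40, 13), rng.normal(20, 90, 24)
        res = sx.welch_t(a, b)
        t, df, p = welch_formula(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_antisymmetric_in_sample_order(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 12)
        assert sx.welch_t(a, b).statistic == pytest.approx(
            -sx.welch_t(b, a).statistic)

    def test_one_tailed_p_at_group_difference_scale(self):
        # t = 2.35 at df = 28.3 sits near p = 0.013 one-tailed
        import scipy.stats as st
        assert st.t.sf(2.35, 28.3) == pytest.approx(0.013, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sx.welch_t([1.0, 1.0], [2.0, 2.0])


class TestCohensD:
    @pytest.mark.parametrize("ma, sa, mb, sb, expected", [
        (248.0, 56.0, 232.0, 51.0, 0.3),
        (261.0, 100.0, 193.0, 27.0, 0.9),
        (221.0, 49.0, 178.0, 30.0, 1.1),
    ])
    def test_rms_pooled_group_effects(self, ma, sa, mb, sb, expected):
        assert round(sx.cohens_d_paired(ma, sa, mb, sb), 1) == expected

    def test_rejects_double_zero_sd(self):
        with pytest.raises(ValueError):
            sx.cohens_d_paired(1.0, 0.0, 2.0, 0.0)


class TestLevene:
    def test_df_for_two_groups_of_24(self):
        rng = np.random.default_rng(5)
        res = sx.levene_test(rng.normal(0, 100, 24), rng.normal(0, 27, 24))
        assert res.df == (1, 46)

    def test_identical_samples_give_zero_f(self):
        a = np.array([1.0, 5.0, 9.0, 2.0])
        res = sx.levene_test(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_anova_on_deviations(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 3, 11), rng.normal(2, 1, 7)
        res = sx.levene_test(a, b)
        f, p = levene_formula(a, b)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestRankTests:
    def test_all_positive_differences_give_maximal_v(self):
        res = sx.rank_tests([3.0, 5.0, 7.0], [1.0, 2.0, 3.0], paired=True)
        assert res.statistic == 6.0  # 1+2+3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_signed_rank_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.5, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        res = sx.rank_tests(a, b, paired=True)
        v, p = signed_rank_exact(a - b)
        assert res.statistic == v
        assert res.p_value == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rank_sum_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed + 10)
        a, b = rng.normal(1, 1, 5), rng.normal(0, 1, 6)
        res = sx.rank_tests(a, b, paired=False)
        w, p = rank_sum_exact(a, b)
        assert res.statistic == w
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_fully_separated_samples_hit_extremes(self):
        lo, hi = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0, 13.0]
        assert sx.rank_tests(hi, lo, paired=False).statistic == 12  # n1*n2
        assert sx.rank_tests(lo, hi, paired=False).statistic == 0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            sx.rank_tests([1.0, 2.0], [1.0, 2.0], paired=True)


class TestChiSquare:
    def test_gender_table(self):
        # male/female counts for patients, controls, relatives
        res = sx.chi_square_independence([[3, 10, 2], [10, 14, 8]])
        assert round(res.statistic, 2) == 2.17
        assert res.df == 2
        assert round(res.p_value, 2) == 0.34

    def test_table_equal_to_expectation_gives_zero(self):
        res = sx.chi_square_independence([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        table = [[7, 3], [2, 9]]
        res = sx.chi_square_independence(table)
        chi2, df = chi2_formula(table)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.df == df

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            sx.chi_square_independence([[0, 0], [1, 2]])


def long_frame(rng, sizes=(13, 24, 10), effects=(0.0, 0.0, 0.0)):
    rows = []
    for (g, n), eff in zip(zip(("patient", "control", "relative"), sizes), effects):
        for i in range(n):
            base = rng.normal(1000, 150)
            for task, shift in (("color", 0.0), ("landolt", eff)):
                rows.append(dict(subject_id=f"{g}{i}", group=g, task=task,
                                 y=base + shift + rng.normal(0, 40)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_df_triples_for_full_cohort(self):
        df = long_frame(np.random.default_rng(7))
        out = {r.name: r for r in sx.mixed_anova(df, dv="y")}
        assert out["ANOVA group"].df == (2, 44)
        assert out["ANOVA task"].df == (1, 44)
        assert out["ANOVA task x group"].df == (2, 44)

    def test_identical_tasks_give_zero_task_f(self):
        df = long_frame(np.random.default_rng(8))
        wide = df.pivot_table(index=["subject_id", "group"], columns="task",
                              values="y").reset_index()
        wide["landolt"] = wide["color"]
        dup = wide.melt(id_vars=["subject_id", "group"], var_name="task",
                        value_name="y")
        out = {r.name: r for r in sx.mixed_anova(dup, dv="y")}
        assert out["ANOVA task"].statistic == pytest.approx(0.0, abs=1e-6)

    def test_matches_sums_of_squares_decomposition(self):
        df = long_frame(np.random.default_rng(9), sizes=(6, 6, 6),
                        effects=(-10.0, -60.0, -40.0))
        out = {r.name: r for r in sx.mixed_anova(df, dv="y")}
        oracle = mixed_anova_ss(df, "y", "task", "subject_id", "group")
        assert out["ANOVA group"].statistic == pytest.approx(
            oracle["group"][0], abs=1e-8)
        assert out["ANOVA task"].statistic == pytest.approx(
            oracle["task"][0], abs=1e-8)
        assert out["ANOVA task x group"].statistic == pytest.approx(
            oracle["interaction"][0], abs=1e-8)

    def test_subject_missing_a_level_excluded(self):
        df = long_frame(np.random.default_rng(10), sizes=(4, 4, 4))
        df = df.drop(df[(df.subject_id == "patient0") & (df.task == "color")].index)
        out = {r.name: r for r in sx.mixed_anova(df, dv="y")}
        assert out["ANOVA group"].df == (2, 8)  # 11 complete subjects, 3 groups


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = sx.pearson_r(x, 2 * x + 1)
        assert res.effect_size == pytest.approx(1.0)

    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=13), rng.normal(size=13)
        assert sx.pearson_r(x, y).df == 11

    def test_t_statistic_closed_form(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=13)
        y = 0.2 * x + rng.normal(size=13)
        res = sx.pearson_r(x, y)
        r = res.effect_size
        assert res.statistic == pytest.approx(r * np.sqrt(11 / (1 - r ** 2)))

    def test_weak_correlation_scale(self):
        # r = 0.17 with n = 13 corresponds to t ~ 0.57
        t = 0.17 * np.sqrt((13 - 2) / (1 - 0.17 ** 2))
        assert round(t, 2) == 0.57

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sx.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert sx.power_paired_t(0.0, 10, alpha=0.05) == pytest.approx(0.05)

    def test_large_effect_small_sample_reaches_099(self):
        assert sx.power_paired_t(2.0, 10, alpha=0.05, tails=2) >= 0.99

    def test_matches_monte_carlo_rejection_rate(self):
        power = sx.power_paired_t(1.0, 10, alpha=0.05, tails=2)
        mc = monte_carlo_paired_power(1.0, 10, 0.05, n_reps=100_000, seed=99)
        assert power == pytest.approx(mc, abs=0.01)

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestPower
        for d, n in ((0.5, 12), (1.0, 8), (2.0, 10)):
            ref = TTestPower().power(effect_size=d, nobs=n, alpha=0.05,
                                     alternative="two-sided")
            assert sx.power_paired_t(d, n) == pytest.approx(ref, abs=1e-9)

    def test_monotone_in_n_and_effect(self):
        by_n = [sx.power_paired_t(1.0, n) for n in (4, 8, 16, 32, 64)]
        assert all(b > a for a, b in zip(by_n, by_n[1:]))
        by_d = [sx.power_paired_t(d, 10) for d in (0.2, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(by_d, by_d[1:]))
        assert sx.power_paired_t(1.0, 500) > 0.999999

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sx.power_paired_t(1.0, 1)
        with pytest.raises(ValueError):
            sx.power_paired_t(1.0, 10, alpha=1.5)
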