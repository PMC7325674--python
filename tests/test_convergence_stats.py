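"""Distribution summaries, ANOVA, post hoc procedures, convergence selection,
Thompson Tau outlier screening."""

import numpy as np
import pytest
from scipy import stats

import phylosample as ps
from phylosample.convergence_stats import build_convergence_report, posthoc_pairwise


class TestGroupSummary:
    def test_constant_group_zero_sd(self):
        (s,) = ps.group_summary({0.1: [0.1, 0.1, 0.1]}).values()
        assert s.sd == pytest.approx(0.0, abs=1e-15)

    def test_sample_sd_uses_n_minus_one(self):
        (s,) = ps.group_summary({0.1: [1, 2, 3, 4]}).values()
        assert s.sd == pytest.approx(np.sqrt(5 / 3))

    def test_percentiles_linear_interpolation(self):
        (s,) = ps.group_summary({0.1: list(range(1, 101))}).values()
        assert s.percentiles[25] == pytest.approx(25.75)
        assert s.percentiles[50] == pytest.approx(50.5)

    def test_outliers_outside_whiskers(self):
        values = list(range(1, 101))
        (s,) = ps.group_summary({0.1: values}).values()
        assert all(v < s.percentiles[10] or v > s.percentiles[90] for v in s.outliers)
        assert s.outliers  # a uniform sample has points beyond the 10/90 whiskers

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ps.group_summary({0.1: []})


class TestOneWayAnova:
    def test_equal_means_give_zero_f(self):
        res = ps.one_way_anova({1: [1.0, 2.0, 3.0], 2: [2.0, 1.0, 3.0]})
        assert res.F == pytest.approx(0.0)

    def test_hand_computed_example(self):
        res = ps.one_way_anova({1: [1, 2, 3], 2: [2, 3, 4], 3: [3, 4, 5]})
        assert res.F == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2, 6)

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(0.5, size=15)
        res = ps.one_way_anova({1: a, 2: b})
        t, p = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2)
        assert res.p == pytest.approx(p)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = {i: rng.normal(i * 0.2, 1.0, size=20) for i in range(4)}
        res = ps.one_way_anova(groups)
        F, p = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(F)
        assert res.p == pytest.approx(p)

    def test_degenerate_all_identical_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ps.one_way_anova({1: [2.0, 2.0], 2: [2.0, 2.0]})

    def test_null_p_values_uniform(self):
        # size-alpha behavior: KS test of the p-value distribution under H0
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(2000):
            groups = {i: rng.normal(size=8) for i in range(3)}
            pvals.append(ps.one_way_anova(groups).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestPosthocPairwise:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        groups = {i: base.copy() for i in range(3)}
        for proc in ("tukey", "bonferroni", "scheffe"):
            table = ps.posthoc_pairwise(groups, proc, alpha=0.05)
            assert not table.significant.any()

    def test_separated_groups_significant_by_all(self):
        rng = np.random.default_rng(7)
        groups = {1: rng.normal(0, 1, 30), 2: rng.normal(10, 1, 30)}
        for proc in ("tukey", "bonferroni", "scheffe"):
            table = ps.posthoc_pairwise(groups, proc, alpha=0.05)
            assert table.significant.all()

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        for _ in range(50):
            k = int(rng.integers(3, 6))
            n = int(rng.integers(5, 15))
            data = [rng.normal(rng.normal(0, 1), 1.0, size=n) for _ in range(k)]
            ours = ps.posthoc_pairwise({i: d for i, d in enumerate(data)}, "tukey", 0.05)
            values = np.concatenate(data)
            labels = np.repeat(np.arange(k), n)
            ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
            # statsmodels reports meandiffs and adjusted p-values pair by pair
            np.testing.assert_allclose(-ours["diff"].to_numpy(), ref.meandiffs, atol=1e-8)
            np.testing.assert_allclose(ours["p"].to_numpy(), ref.pvalues, atol=1e-6)

    def test_bonferroni_implies_unadjusted_below_alpha_over_m(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            groups = {i: rng.normal(rng.normal(), 1, size=10) for i in range(4)}
            table = ps.posthoc_pairwise(groups, "bonferroni", alpha=0.05)
            m = len(table)
            df2 = sum(len(v) for v in groups.values()) - len(groups)
            for _, row in table.iterrows():
                raw_p = 2 * stats.t.sf(abs(row.stat), df2)
                if row.significant:
                    assert raw_p < 0.05 / m

    def test_scheffe_never_more_liberal_than_tukey(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            groups = {i: rng.normal(0.3 * i, 1, size=12) for i in range(4)}
            tukey = ps.posthoc_pairwise(groups, "tukey", alpha=0.05)
            scheffe = ps.posthoc_pairwise(groups, "scheffe", alpha=0.05)
            assert not (scheffe.significant & ~tukey.significant).any()


class TestConvergenceEffort:
    def test_single_distribution_immediate_plateau(self):
        rng = np.random.default_rng(11)
        groups = {e: rng.normal(0.5, 0.1, 30) for e in (0.1, 0.2, 0.3)}
        assert ps.convergence_effort(groups, alpha=0.01) == 0.1

    def test_strictly_separated_groups_no_plateau(self):
        rng = np.random.default_rng(12)
        groups = {e: rng.normal(10 - 20 * e, 0.05, 30) for e in (0.1, 0.2, 0.3)}
        assert ps.convergence_effort(groups, alpha=0.01) is None

    def test_plateau_at_fourth_of_five_efforts(self):
        # decreasing means that level off between the 4th and 5th efforts
        means = {0.001: 1.0, 0.01: 0.6, 0.1: 0.3, 0.2: 0.1, 0.3: 0.1}
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            groups = {e: rng.normal(mu, 0.05, 30) for e, mu in means.items()}
            if ps.convergence_effort(groups, alpha=0.01) == 0.2:
                hits += 1
        assert hits > n_seeds / 2

    def test_type_one_error_within_binomial_bounds(self):
        # adjacent comparison under the null: selection of the first effort
        # should fail at rate <= alpha (up to binomial noise)
        alpha = 0.01
        n_sims = 1000
        rng = np.random.default_rng(13)
        false_moves = 0
        for _ in range(n_sims):
            groups = {0.1: rng.normal(size=30), 0.2: rng.normal(size=30)}
            if ps.convergence_effort(groups, alpha=alpha) is None:
                false_moves += 1
        bound = n_sims * alpha + 3 * np.sqrt(n_sims * alpha * (1 - alpha))
        assert false_moves <= bound


class TestThompsonTau:
    def test_symmetric_values_no_outliers(self):
        assert ps.thompson_tau_outliers([1, 2, 3, 4, 5]) == []

    def test_single_gross_outlier_flagged(self):
        assert ps.thompson_tau_outliers([10, 10, 10, 10, 50]) == [50.0]

    def test_all_equal_no_outliers(self):
        assert ps.thompson_tau_outliers([7.0] * 6) == []

    def test_iterative_removal_of_two_outliers(self):
        values = [10.0] * 10 + [100.0, 120.0]
        flagged = ps.thompson_tau_outliers(values)
        assert set(flagged) == {100.0, 120.0}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ps.thompson_tau_outliers([1.0, 2.0])


class TestReport:
    def test_full_report_fields(self):
        rng = np.random.default_rng(14)
        groups = {e: list(rng.normal(1 - e, 0.1, 30)) for e in (0.1, 0.2, 0.3)}
        report = build_convergence_report(groups, alpha=0.01)
        assert report.efforts == [0.1, 0.2, 0.3]
        assert set(report.posthoc) == {"tukey", "bonferroni", "scheffe"}
        assert report.anova.df1 == 2
        assert report.selected_effort in (0.1, 0.2, 0.3, None)

    def test_percentiles_ordered(self):
        rng = np.random.default_rng(15)
        summaries = ps.group_summary({0.1: rng.normal(size=50)})
        pct = summaries[0.1].percentiles
        assert pct[10] <= pct[25] <= pct[50] <= pct[75] <= pct[90]

    def test_boxplot_export(self, tmp_path):
        rng = np.random.default_rng(16)
        groups = {e: rng.normal(1 - e, 0.1, 30) for e in (0.1, 0.2, 0.3)}
        out = tmp_path / "box.png"
        from phylosample.convergence_stats import plot_effort_distributions

        plot_effort_distributions(groups, str(out))
        assert out.stat().st_size > 0
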