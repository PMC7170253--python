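import numpy as np
import pandas as pd
import pytest

from prognosig.errors import ConfigError, DegenerateError
from prognosig.survival_stats import (chisq_yates, cox_backward_wald,
                                      cox_univariate_group, km_logrank,
                                      two_group_tests, univariate_prescreen)
from prognosig.types import GroupAssignment

from conftest import make_survival
from oracles import brute_force_cox_coef, hand_logrank, welch_t, yates_chi2


def group_of(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return GroupAssignment(
        groups=pd.Series(labels, index=ids), cutoff=0.0, cutoff_rule="test")


class TestKmLogrank:
    def test_identical_groups_give_zero_statistic(self):
        # same times/events duplicated across the two groups
        surv = make_survival([1, 2, 3, 4] * 2, [1, 1, 0, 1] * 2)
        groups = group_of(["low"] * 4 + ["high"] * 4)
        km, stat, p = km_logrank(groups, surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_eight_sample_hand_oracle(self):
        # frozen from the observed-minus-expected log-rank arithmetic:
        # O=4, E=2.82857..., V=1.48489..., stat=0.9241341, p=0.3363918
        surv = make_survival([1, 3, 5, 7, 2, 4, 6, 8],
                             [1, 1, 1, 1, 1, 1, 0, 1])
        groups = group_of(["low"] * 4 + ["high"] * 4)
        _, stat, p = km_logrank(groups, surv)
        assert stat == pytest.approx(0.924134139637163, rel=1e-9)
        assert p == pytest.approx(0.33639181841323745, rel=1e-9)
        oracle_stat, oracle_p = hand_logrank(
            surv.time, surv.event, np.array([0] * 4 + [1] * 4))
        assert stat == pytest.approx(oracle_stat, rel=1e-9)
        assert p == pytest.approx(oracle_p, rel=1e-9)

    def test_km_no_censoring_equals_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        surv = make_survival(times * 2, [1] * 10)
        groups = group_of(["low"] * 5 + ["high"] * 5)
        km, _, _ = km_logrank(groups, surv)
        tab = km.curves["low"]
        for t_obs, frac in zip(times, [0.8, 0.6, 0.4, 0.2, 0.0]):
            est = tab.loc[tab["time"] == t_obs, "survival"].iloc[0]
            assert est == pytest.approx(frac)

    def test_survival_curve_monotone_from_one(self):
        rng = np.random.default_rng(0)
        surv = make_survival(rng.exponential(5, 40), rng.integers(0, 2, 40))
        if surv.n_events < 1:
            pytest.skip("no events drawn")
        groups = group_of(["low"] * 20 + ["high"] * 20)
        km, _, _ = km_logrank(groups, surv)
        for tab in km.curves.values():
            s = tab["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_relabeling_invariance(self):
        surv = make_survival([1, 3, 5, 7, 2, 4, 6, 8], [1, 1, 1, 1, 1, 1, 0, 1])
        g1 = group_of(["low"] * 4 + ["high"] * 4)
        g2 = group_of(["high"] * 4 + ["low"] * 4)
        _, s1, p1 = km_logrank(g1, surv)
        _, s2, p2 = km_logrank(g2, surv)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_errors(self):
        surv = make_survival([1, 2, 3], [1, 1, 1])
        groups = group_of(["low", "low", "low"])
        with pytest.raises(DegenerateError):
            km_logrank(groups, surv)

    def test_power_on_planted_cohort(self, small_planted_cohort):
        from prognosig.expression_io import compute_cpm, log_transform
        from prognosig.scoring import compute_score, dichotomize
        from prognosig.types import Signature

        expr, surv, truth = small_planted_cohort
        logged = log_transform(compute_cpm(expr))
        sig = Signature("truth", tuple((g, float(s)) for g, s, _ in truth.planted_genes))
        groups = dichotomize(compute_score(logged, sig))
        _, _, p = km_logrank(groups, surv)
        assert p < 0.05


class TestCoxUnivariateGroup:
    def test_identical_groups_hr_near_one(self):
        surv = make_survival([1, 2, 3, 4, 5] * 2, [1, 1, 1, 0, 1] * 2)
        groups = group_of(["low"] * 5 + ["high"] * 5)
        report = cox_univariate_group(groups, surv)
        assert report.hr("high") == pytest.approx(1.0, abs=1e-6)

    def test_matches_shared_brute_force_oracle(self, six_sample_survival):
        groups = group_of(["high", "low", "high", "low", "high", "low"])
        report = cox_univariate_group(groups, six_sample_survival)
        oracle = brute_force_cox_coef(
            six_sample_survival.time, six_sample_survival.event,
            np.array([1, 0, 1, 0, 1, 0.0]))
        assert np.log(report.hr("high")) == pytest.approx(oracle, abs=1e-5)

    def test_label_swap_inverts_hr(self, tied_survival):
        labels = ["high", "low"] * 5
        swapped = ["low", "high"] * 5
        r1 = cox_univariate_group(group_of(labels), tied_survival)
        r2 = cox_univariate_group(group_of(swapped), tied_survival)
        assert r1.hr("high") == pytest.approx(1.0 / r2.hr("high"), rel=1e-4)

    def test_no_events_in_one_group_warns(self):
        surv = make_survival([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        groups = group_of(["low"] * 3 + ["high"] * 3)
        report = cox_univariate_group(groups, surv)
        assert any("monotone" in w for w in report.warnings)


class TestCoxBackwardWald:
    def _synthetic(self, seed=21, n=300):
        rng = np.random.default_rng(seed)
        true = rng.normal(size=n)
        noise1 = rng.normal(size=n)
        noise2 = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(1.0 * true))
        surv = make_survival(t, np.ones(n, dtype=int))
        X = pd.DataFrame({"true_cov": true, "noise_a": noise1, "noise_b": noise2},
                         index=surv.sample_ids)
        return X, surv

    def test_all_significant_single_step(self):
        rng = np.random.default_rng(2)
        n = 300
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.8 * a + 0.8 * b))
        surv = make_survival(t, np.ones(n, dtype=int))
        X = pd.DataFrame({"a": a, "b": b}, index=surv.sample_ids)
        report = cox_backward_wald(X, surv)
        assert len(report.steps) == 1
        assert set(report.summary.index) == {"a", "b"}

    def test_noise_removed_true_survives(self):
        X, surv = self._synthetic()
        report = cox_backward_wald(X, surv)
        assert list(report.summary.index) == ["true_cov"]
        assert report.p("true_cov") < 0.05
        # step history strictly decreasing in covariate count
        sizes = [len(s) for s in report.steps]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(sizes)) == len(sizes)

    def test_removal_order_follows_initial_wald_p(self):
        X, surv = self._synthetic(seed=33)
        report = cox_backward_wald(X, surv)
        first = report.step_summaries[0]
        removed_first = (set(report.steps[0]) - set(report.steps[1])).pop()
        assert removed_first == first["p"].idxmax()

    def test_removal_alpha_one_removes_nothing(self):
        X, surv = self._synthetic(seed=5)
        report = cox_backward_wald(X, surv, removal_alpha=1.0000001)
        assert len(report.steps) == 1
        assert set(report.summary.index) == set(X.columns)

    def test_no_covariates_rejected(self):
        _, surv = self._synthetic()
        with pytest.raises(ConfigError):
            cox_backward_wald(pd.DataFrame(index=surv.sample_ids), surv)


class TestUnivariatePrescreen:
    def test_filters_noise(self):
        X, surv = TestCoxBackwardWald()._synthetic(seed=8)
        kept = univariate_prescreen(X, surv, alpha=0.05)
        assert "true_cov" in kept
        assert "noise_a" not in kept or "noise_b" not in kept


class TestTwoGroupTests:
    def test_identical_groups(self):
        res = two_group_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_welch_fixture_matches_closed_form(self):
        x = [1.1, 2.3, 3.1, 4.0, 5.2]
        y = [2.0, 3.5, 4.1, 5.5]
        res = two_group_tests(x, y)
        # frozen from the textbook Welch/Satterthwaite computation
        assert res.statistic == pytest.approx(-0.6292914734838887, rel=1e-10)
        assert res.p == pytest.approx(0.54974399554905, rel=1e-10)
        t_oracle, p_oracle = welch_t(x, y)
        assert res.statistic == pytest.approx(t_oracle, rel=1e-12)
        assert res.p == pytest.approx(p_oracle, rel=1e-12)

    def test_paired_constant_difference_degenerate(self):
        res = two_group_tests([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)
        assert res.degenerate

    def test_paired_matches_scipy(self):
        from scipy import stats

        x = [1.0, 2.5, 3.0, 4.5]
        y = [1.2, 2.0, 3.9, 4.0]
        res = two_group_tests(x, y, paired=True)
        t, p = stats.ttest_rel(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_paired_length_mismatch(self):
        with pytest.raises(ConfigError):
            two_group_tests([1, 2, 3], [1, 2], paired=True)

    def test_too_small_groups(self):
        with pytest.raises(ConfigError):
            two_group_tests([1.0], [1.0, 2.0])


class TestChisqYates:
    def test_balanced_table_zero(self):
        stat, p = chisq_yates([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        stat, p = chisq_yates([[10, 10], [20, 5]])
        # frozen from sum((|O-E|-0.5)^2/E)
        assert stat == pytest.approx(3.25125, rel=1e-9)
        assert p == pytest.approx(0.07136901092402102, rel=1e-9)
        o_stat, o_p = yates_chi2([[10, 10], [20, 5]])
        assert stat == pytest.approx(o_stat, rel=1e-12)
        assert p == pytest.approx(o_p, rel=1e-12)

    def test_transpose_invariance(self):
        a = chisq_yates([[10, 10], [20, 5]])
        b = chisq_yates([[10, 20], [10, 5]])
        assert a[0] == pytest.approx(b[0])

    def test_zero_margin_errors(self):
        with pytest.raises(DegenerateError):
            chisq_yates([[0, 0], [5, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ConfigError):
            chisq_yates([[1.5, 2], [3, 4]])
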