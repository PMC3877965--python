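import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from pathsurv import (
    cox_multivariate,
    cox_univariate_sign,
    dichotomize_at_median,
    km_curve,
    logrank_test,
)
from pathsurv.survival import GroupLabels

from conftest import make_surv


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def logrank_oracle(time, event, high):
    """Brute-force log-rank chi-square: explicit loop over event times."""
    time, event, high = np.asarray(time, float), np.asarray(event), np.asarray(high, bool)
    oe, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & high).sum()
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe * oe / var if var > 0 else np.nan


def cox_loglik_oracle(beta, time, event, x):
    """Breslow partial log-likelihood, direct double loop (no ties assumed away)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.asarray(x)[risk])))
    return ll


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

class TestDichotomize:
    @pytest.mark.parametrize(
        "values,cut,high_idx",
        [
            ([1, 2, 3, 4], 2.5, [2, 3]),       # even n: mean of middle order stats
            ([1, 2, 3], 2.0, [1, 2]),          # odd n: >= median rule includes the median
        ],
    )
    def test_median_rule(self, values, cut, high_idx):
        labels = dichotomize_at_median(values)
        assert labels.cut == cut
        assert list(np.flatnonzero(labels.high)) == high_idx

    def test_all_identical_goes_high_with_warning(self):
        with pytest.warns(UserWarning, match="single group"):
            labels = dichotomize_at_median([5, 5, 5, 5])
        assert labels.high.all() and labels.degenerate


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        # two identical copies of the same survival experience
        surv = make_surv([1, 3, 5, 1, 3, 5], [1, 1, 0, 1, 1, 0])
        labels = GroupLabels(high=np.array([True] * 3 + [False] * 3), cut=0.0)
        res = logrank_test(surv, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_symmetry(self, toy_surv):
        high = np.array([True, False, True, False, True, False])
        a = logrank_test(toy_surv, GroupLabels(high=high, cut=0.0))
        b = logrank_test(toy_surv, GroupLabels(high=~high, cut=0.0))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_six_patient_toy_matches_brute_force_and_permutation(self, toy_surv):
        """Statistic equals the explicit O-E/variance sums; chi-square p is
        consistent with the exact permutation distribution over labelings."""
        high = np.array([True, True, True, False, False, False])
        res = logrank_test(toy_surv, GroupLabels(high=high, cut=0.0))
        t, e = toy_surv["time"].to_numpy(), toy_surv["event"].to_numpy()
        assert res.statistic == pytest.approx(logrank_oracle(t, e, high), rel=1e-12)
        # exact permutation distribution over all 3-vs-3 assignments
        stats_all = []
        for combo in itertools.combinations(range(6), 3):
            h = np.zeros(6, bool)
            h[list(combo)] = True
            stats_all.append(logrank_oracle(t, e, h))
        p_perm = np.mean(np.asarray(stats_all) >= res.statistic - 1e-12)
        assert abs(res.p_value - p_perm) < 0.25  # chi2(1) approximation at n=6

    def test_matches_brute_force_on_random_small_datasets(self):
        """Exhaustive check against the independent oracle for every balanced
        labeling of random datasets with <= 8 patients."""
        rng = np.random.default_rng(5)
        for n in (4, 6, 8):
            for _ in range(3):
                t = rng.exponential(10, n).round(1) + 0.5
                e = rng.integers(0, 2, n)
                e[rng.integers(0, n)] = 1
                surv = make_surv(t, e)
                for combo in itertools.combinations(range(n), n // 2):
                    h = np.zeros(n, bool)
                    h[list(combo)] = True
                    expected = logrank_oracle(t, e, h)
                    if not np.isfinite(expected):
                        continue
                    got = logrank_test(surv, GroupLabels(high=h, cut=0.0))
                    assert got.statistic == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_matches_lifelines_on_larger_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 60
            t = rng.exponential(20, n)
            e = rng.integers(0, 2, n)
            e[0] = 1
            h = rng.random(n) < 0.5
            h[0], h[1] = True, False
            surv = make_surv(t, e)
            mine = logrank_test(surv, GroupLabels(high=h, cut=0.0))
            ref = ll_logrank(t[h], t[~h], e[h], e[~h])
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_and_zero_events_rejected(self, toy_surv):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_test(toy_surv, GroupLabels(high=np.ones(6, bool), cut=0.0))
        dead = make_surv([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(dead, GroupLabels(high=np.array([1, 1, 0, 0], bool), cut=0.0))


# ---------------------------------------------------------------------------
# univariate Cox sign
# ---------------------------------------------------------------------------

class TestCoxUnivariate:
    def test_risk_decreasing_in_time_gives_positive_sign(self):
        surv = make_surv([1, 2, 3, 4, 5, 6], [1] * 6)
        covariate = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]  # higher value, earlier death
        fit = cox_univariate_sign(surv, covariate)
        assert fit.sign == 1

    def test_negation_symmetry(self, toy_surv):
        x = np.array([0.3, -1.2, 0.7, 2.2, -0.4, 1.1])
        a = cox_univariate_sign(toy_surv, x)
        b = cox_univariate_sign(toy_surv, -x)
        assert a.coefficient == pytest.approx(-b.coefficient, rel=1e-8)

    def test_constant_covariate_degenerate(self, toy_surv):
        fit = cox_univariate_sign(toy_surv, np.ones(6))
        assert fit.sign == 0 and fit.degenerate

    def test_coefficient_maximizes_partial_likelihood(self):
        """The returned beta beats a grid of alternatives under an
        independently coded Breslow partial log-likelihood."""
        rng = np.random.default_rng(3)
        n = 40
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.8 * x))
        e = np.ones(n, int)
        surv = make_surv(t, e)
        fit = cox_univariate_sign(surv, x)
        ll_hat = cox_loglik_oracle(fit.coefficient, t, e, x)
        for delta in (-0.5, -0.1, 0.1, 0.5):
            assert ll_hat >= cox_loglik_oracle(fit.coefficient + delta, t, e, x)

    def test_matches_lifelines_coefficient(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 70
        x = rng.standard_normal(n)
        t = rng.exponential(10 * np.exp(-0.5 * x))
        e = rng.integers(0, 2, n)
        e[:5] = 1
        surv = make_surv(t, e)
        fit = cox_univariate_sign(surv, x)
        df = pd.DataFrame({"time": t, "event": e, "x": x})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "time", "event")
        assert fit.coefficient == pytest.approx(float(cph.params_["x"]), abs=1e-4)

    def test_sign_agrees_with_logrank_direction_on_strong_effects(self):
        """High-group-worse genes must fit positive Cox coefficients."""
        rng = np.random.default_rng(21)
        agree = 0
        trials = 40
        for _ in range(trials):
            n = 100
            x = rng.standard_normal(n)
            t = rng.exponential(20 * np.exp(-1.5 * x))
            surv = make_surv(t, np.ones(n, int))
            fit = cox_univariate_sign(surv, x)
            labels = dichotomize_at_median(x)
            km = km_curve(surv, labels)
            high_worse = km.medians["High"] < km.medians["Low"]
            agree += int((fit.sign == 1) == high_worse)
        assert agree >= int(0.99 * trials)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKMCurve:
    def test_product_limit_by_hand(self):
        surv = make_surv([1, 2, 3], [1, 1, 1])
        km = km_curve(surv)
        tab = km.tables["All"].set_index("time")["survival"]
        assert tab.loc[1.0] == pytest.approx(2 / 3)
        assert tab.loc[2.0] == pytest.approx(1 / 3)
        assert tab.loc[3.0] == pytest.approx(0.0)
        assert km.medians["All"] == pytest.approx(2.0)

    def test_all_censored_flat_curve_undefined_median(self):
        surv = make_surv([5, 6, 7], [0, 0, 0])
        km = km_curve(surv)
        assert (km.tables["All"]["survival"] == 1.0).all()
        assert np.isinf(km.medians["All"])

    def test_planted_risk_group_has_shorter_median(self, planted_cohort):
        cohort, genes, betas = planted_cohort
        g = genes[0]  # beta = +1
        labels = dichotomize_at_median(cohort.expression.loc[g].to_numpy())
        km = km_curve(cohort.survival, labels)
        assert km.medians["High"] < km.medians["Low"]


# ---------------------------------------------------------------------------
# multivariate Cox
# ---------------------------------------------------------------------------

class TestCoxMultivariate:
    def test_single_covariate_reduces_to_univariate(self, planted_cohort):
        cohort, genes, _ = planted_cohort
        x = cohort.expression.loc[genes[0]]
        uni = cox_univariate_sign(cohort.survival, x.to_numpy())
        multi = cox_multivariate(cohort.survival, pd.DataFrame({"x": x.to_numpy()}))
        assert multi.coef[0] == pytest.approx(uni.coefficient, abs=5e-4)

    def test_all_zero_covariate_rejected(self, toy_surv):
        covs = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6], "z": [0.0] * 6})
        with pytest.raises(ValueError, match="z"):
            cox_multivariate(toy_surv, covs)

    def test_score_dominates_noise_covariates(self):
        """When only the risk score drives hazard, its coefficient should be
        significant and noise covariates not, in nearly all replications."""
        rng = np.random.default_rng(31)
        hits, noise_fp = 0, 0
        reps = 25
        for _ in range(reps):
            n = 300
            score = rng.integers(0, 17, n).astype(float)
            age = rng.normal(60, 8, n)
            noise = rng.standard_normal(n)
            t = rng.exponential(50 * np.exp(-0.25 * (score - 8)))
            surv = make_surv(t, np.ones(n, int))
            fit = cox_multivariate(
                surv, pd.DataFrame({"score": score, "age": age, "noise": noise})
            )
            p = dict(zip(fit.names, fit.p_values))
            hits += int(p["score"] < 0.05)
            noise_fp += int(p["noise"] < 0.05)
        assert hits >= int(0.9 * reps)
        assert noise_fp <= int(0.3 * reps)
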