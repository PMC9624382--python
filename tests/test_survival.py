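"""Survival estimators checked against hand-written oracles.

The oracles here (product-limit loop, O-E log-rank loop, Efron partial
likelihood grid search) are deliberately naive re-implementations that
share no code with the package.
"""

import numpy as np
import pandas as pd
import pytest

from irgpair import cox_multivariate, cox_univariate, km_estimate, logrank_test

from conftest import make_survival


# ---------------------------------------------------------------- oracles

def km_oracle(times, events):
    """Naive product-limit estimate at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_oracle(ta, ea, tb, eb):
    """Two-group O-E log-rank chi-squared over the pooled risk sets."""
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    oe, var = 0.0, 0.0
    for t in sorted(set(t_all[e_all == 1])):
        at_risk = t_all >= t
        n = at_risk.sum()
        na = (at_risk & (group == 0)).sum()
        d = ((t_all == t) & (e_all == 1)).sum()
        da = ((t_all == t) & (e_all == 1) & (group == 0)).sum()
        oe += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return oe**2 / var


def efron_loglik(beta, times, events, x):
    """Efron-corrected Cox partial log-likelihood for one covariate."""
    times, events, x = map(np.asarray, (times, events, x))
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        sum_tied_eta = beta * x[tied].sum()
        exp_risk = np.exp(beta * x[risk]).sum()
        exp_tied = np.exp(beta * x[tied]).sum()
        ll += sum_tied_eta
        for ell in range(d):
            ll -= np.log(exp_risk - (ell / d) * exp_tied)
    return ll


def grid_mle(times, events, x, lo=-4.0, hi=4.0):
    grid = np.arange(lo, hi, 1e-3)
    lls = np.array([efron_loglik(b, times, events, x) for b in grid])
    b0 = grid[lls.argmax()]
    fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-5)
    lls = np.array([efron_loglik(b, times, events, x) for b in fine])
    return fine[lls.argmax()]


# ------------------------------------------------------------------ tests

class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        curve = km_estimate(make_survival([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(curve.times, [1, 2, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_all_censored_constant_one(self):
        with pytest.warns(UserWarning, match="no events"):
            curve = km_estimate(make_survival([1, 2, 3], [0, 0, 0]))
        assert curve.survival_at(100.0) == 1.0

    def test_single_event(self):
        curve = km_estimate(make_survival([5], [1]))
        assert curve.survival_at(5) == 0.0

    def test_matches_oracle_with_censoring_and_ties(self, rng):
        times = rng.integers(1, 15, size=40).astype(float)
        events = rng.integers(0, 2, size=40)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(make_survival(times, events))
        t_o, s_o = km_oracle(times, events)
        np.testing.assert_allclose(curve.times, t_o)
        np.testing.assert_allclose(curve.survival, s_o, atol=1e-12)

    def test_record_order_invariance(self, rng):
        times = [3.0, 1.0, 7.0, 2.0, 2.0]
        events = [1, 0, 1, 1, 0]
        base = km_estimate(make_survival(times, events))
        perm = rng.permutation(5)
        shuf = km_estimate(make_survival(np.array(times)[perm], np.array(events)[perm]))
        np.testing.assert_allclose(base.survival, shuf.survival)

    def test_late_censoring_adds_no_steps(self):
        """A censored observation beyond the last event adds no step to
        the curve; it only enlarges earlier risk sets, so the estimate
        can shift weakly upward but never drops further."""
        base = km_estimate(make_survival([1, 2, 3], [1, 1, 0]))
        ext = km_estimate(make_survival([1, 2, 3, 99], [1, 1, 0, 0]))
        np.testing.assert_allclose(base.times, ext.times)
        assert np.all(ext.survival >= base.survival - 1e-12)

    def test_survival_at_is_right_continuous_step(self):
        curve = km_estimate(make_survival([1, 2, 3], [1, 1, 1]))
        assert curve.survival_at(0.5) == 1.0
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.7) == pytest.approx(1 / 3)


class TestLogrank:
    def test_identical_groups_null(self):
        g = make_survival([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank_test(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_oracle_four_risk_sets(self):
        a = make_survival([1, 2], [1, 1], prefix="a")
        b = make_survival([3, 4], [1, 1], prefix="b")
        stat, _ = logrank_test(a, b)
        assert stat == pytest.approx(logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1]),
                                     rel=1e-10)

    def test_matches_oracle_random(self, rng):
        ta = rng.exponential(10, 25)
        tb = rng.exponential(20, 30)
        ea = rng.integers(0, 2, 25)
        eb = rng.integers(0, 2, 30)
        ea[0] = eb[0] = 1
        stat, _ = logrank_test(make_survival(ta, ea, "a"), make_survival(tb, eb, "b"))
        assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-8)

    def test_permutation_invariance(self, rng):
        ta, ea = [5.0, 1.0, 9.0], [1, 0, 1]
        tb, eb = [2.0, 8.0], [1, 1]
        base = logrank_test(make_survival(ta, ea, "a"), make_survival(tb, eb, "b"))[0]
        perm = logrank_test(make_survival(ta[::-1], ea[::-1], "a"),
                            make_survival(tb[::-1], eb[::-1], "b"))[0]
        assert base == pytest.approx(perm)

    def test_no_events_errors(self):
        g = make_survival([1, 2], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            logrank_test(g, g)


class TestCoxUnivariate:
    def test_matches_efron_grid_oracle(self, rng):
        n = 20
        x = rng.integers(0, 2, n).astype(float)
        times = rng.integers(1, 10, n).astype(float)  # ties on purpose
        events = rng.integers(0, 2, n)
        events[:4] = 1
        surv = make_survival(times, events)
        fit = cox_univariate(x, surv)
        assert fit.coefficients.iloc[0] == pytest.approx(
            grid_mle(times, events, x), abs=1e-4)

    def test_reparameterization(self, rng):
        n = 60
        x = rng.normal(size=n)
        events = rng.integers(0, 2, n)
        events[:10] = 1
        surv = make_survival(rng.exponential(10, n), events)
        f1 = cox_univariate(x, surv)
        f2 = cox_univariate(2 * x, surv)
        assert f2.coefficients.iloc[0] == pytest.approx(
            f1.coefficients.iloc[0] / 2, rel=1e-6)
        assert f2.p_values.iloc[0] == pytest.approx(f1.p_values.iloc[0], rel=1e-6)

    def test_constant_covariate_errors(self, toy_survival):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(np.ones(3), toy_survival)

    def test_null_covariate_rarely_significant(self):
        """Under independence the Wald test keeps near-nominal size."""
        n_sig = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            n = 200
            x = rng.normal(size=n)
            t = rng.exponential(20, n)
            c = rng.uniform(0, 40, n)
            surv = make_survival(np.minimum(t, c), (t <= c).astype(int))
            fit = cox_univariate(x, surv)
            assert abs(fit.coefficients.iloc[0]) < 1.0
            n_sig += fit.p_values.iloc[0] < 0.05
        assert n_sig <= 5  # >= 90% non-significant

    def test_hazard_ratio_consistency(self, rng):
        n = 80
        x = rng.integers(0, 2, n).astype(float)
        surv = make_survival(rng.exponential(10, n) / (1 + x), np.ones(n))
        fit = cox_univariate(x, surv)
        assert fit.hazard_ratios.iloc[0] == pytest.approx(
            np.exp(fit.coefficients.iloc[0]))
        assert fit.ci_lower.iloc[0] < fit.hazard_ratios.iloc[0] < fit.ci_upper.iloc[0]


class TestCoxMultivariate:
    def test_single_covariate_reduces_to_univariate(self, rng):
        n = 50
        x = rng.normal(size=n)
        surv = make_survival(rng.exponential(10, n) * np.exp(-0.5 * x), np.ones(n))
        uni = cox_univariate(x, surv, name="x")
        multi = cox_multivariate(pd.DataFrame({"x": x}, index=surv.index), surv)
        assert multi.coefficients["x"] == pytest.approx(uni.coefficients["x"], rel=1e-8)

    def test_noise_covariate_barely_moves_signal(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10, n) * np.exp(-1.0 * x)
        surv = make_survival(t, np.ones(n))
        noise = rng.normal(size=n)
        alone = cox_multivariate(pd.DataFrame({"x": x}, index=surv.index), surv)
        joint = cox_multivariate(pd.DataFrame({"x": x, "z": noise}, index=surv.index), surv)
        assert abs(joint.coefficients["x"] - alone.coefficients["x"]) < 0.1

    def test_collinear_covariates_named(self, rng):
        n = 40
        x = rng.normal(size=n)
        surv = make_survival(rng.exponential(10, n), np.ones(n))
        X = pd.DataFrame({"a": x, "b": x}, index=surv.index)
        with pytest.raises(ValueError, match="collinear.*a.*b"):
            cox_multivariate(X, surv)


class TestLogrankCoxAgreement:
    def test_logrank_equals_cox_score_test_tie_free(self, rng):
        """On tie-free data the log-rank statistic is the Cox score test
        of the group indicator; check against a score-test oracle."""
        n = 30
        t = rng.exponential(10, n)
        t += rng.uniform(0, 1e-6, n)  # guarantee no ties
        e = rng.integers(0, 2, n)
        e[:5] = 1
        g = rng.integers(0, 2, n)
        while g.sum() in (0, n):
            g = rng.integers(0, 2, n)
        surv_a = make_survival(t[g == 0], e[g == 0], "a")
        surv_b = make_survival(t[g == 1], e[g == 1], "b")
        stat, _ = logrank_test(surv_a, surv_b)

        # Cox partial-likelihood score test at beta = 0
        u, v = 0.0, 0.0
        for ti in np.sort(t[e == 1]):
            risk = t >= ti
            xr = g[risk].astype(float)
            xi = float(g[(t == ti)][0])
            u += xi - xr.mean()
            v += xr.var()
        assert stat == pytest.approx(u**2 / v, abs=1e-6)
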