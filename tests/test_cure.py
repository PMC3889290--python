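"""Parametric cure-model quantities, likelihood, MLE and diagnostics."""

import numpy as np
import pytest
from scipy import integrate

from curesurv.cure import (
    CureModelParams,
    cure_fraction_ci,
    cure_hazard,
    cure_survival,
    fit_mle,
    gof_pairs,
    model_compare_aic,
    neg_loglik,
)
from curesurv.km import km_fit
from curesurv.simulate import SyntheticConfig, simulate_survival


# --------------------------------------------------------- closed-form checks


def test_survival_closed_forms():
    p = CureModelParams(0.5, 1.5, 20.0)
    assert cure_survival(0.0, p) == 1.0
    assert cure_survival(1e6, p) == pytest.approx(0.5)
    expo = CureModelParams(0.0, 1.0, 10.0)
    assert cure_survival(10.0, expo) == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        cure_survival(-1.0, p)


def test_hazard_closed_forms():
    expo = CureModelParams(0.0, 1.0, 10.0)
    t = np.linspace(0.1, 50, 25)
    assert np.allclose(cure_hazard(t, expo), 0.1)
    cured = CureModelParams(0.5, 1.5, 20.0)
    assert cure_hazard(1e5, cured) == pytest.approx(0.0, abs=1e-12)
    assert (cure_hazard(t, cured) >= 0).all()


def test_survival_equals_exp_neg_integrated_hazard():
    """S(t) = exp(-int_0^t h(u) du) numerically, within 1e-6."""
    p = CureModelParams(0.51, 1.4, 14.0)
    for t_end in (5.0, 15.0, 40.0):
        integral, _ = integrate.quad(lambda u: cure_hazard(u, p), 0.0, t_end, limit=200)
        assert np.exp(-integral) == pytest.approx(cure_survival(t_end, p), abs=1e-6)


# ------------------------------------------------------------- log-likelihood


def test_loglik_all_censored_at_cure_boundary_is_zero():
    p = CureModelParams(1.0, 1.4, 14.0)
    nll = neg_loglik(p, [5.0, 8.0, 12.0], [0, 0, 0])
    assert nll == pytest.approx(0.0, abs=1e-12)


def test_loglik_exponential_closed_form_hand_dataset():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1, 1, 0, 1, 0])
    lam = 7.0
    p = CureModelParams(0.0, 1.0, lam)
    d = events.sum()
    hand = d * np.log(1 / lam) - times.sum() / lam
    assert -neg_loglik(p, times, events, "exponential") == pytest.approx(hand, abs=1e-12)


def test_loglik_agrees_with_independent_formula():
    """Direct density/survival summation oracle over random parameter draws."""
    rng = np.random.default_rng(9)
    times = rng.weibull(1.3, size=50) * 10 + 0.01
    events = (rng.random(50) < 0.6).astype(int)
    for _ in range(100):
        pi = rng.uniform(0.05, 0.9)
        k = rng.uniform(0.4, 3.0)
        lam = rng.uniform(2.0, 40.0)
        f = (k / lam) * (times / lam) ** (k - 1) * np.exp(-((times / lam) ** k))
        s = np.exp(-((times / lam) ** k))
        oracle = np.sum(
            np.where(events == 1, np.log((1 - pi) * f), np.log(pi + (1 - pi) * s))
        )
        ours = -neg_loglik(CureModelParams(pi, k, lam), times, events)
        assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-10)


def test_loglik_event_at_zero_is_error():
    with pytest.raises(ValueError):
        neg_loglik(CureModelParams(0.5, 1.4, 14.0), [0.0, 1.0], [1, 0])


def test_boundary_equivalences_hold_to_1e10():
    """pi=0 cure == Weibull; k=1 Weibull == exponential, on random datasets."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = rng.integers(10, 60)
        times = rng.weibull(1.2, size=n) * rng.uniform(5, 20) + 0.01
        events = (rng.random(n) < rng.uniform(0.3, 0.9)).astype(int)
        k = rng.uniform(0.5, 2.5)
        lam = rng.uniform(2.0, 30.0)
        cure0 = CureModelParams(0.0, k, lam)
        assert neg_loglik(cure0, times, events, "weibull_cure") == pytest.approx(
            neg_loglik(cure0, times, events, "weibull"), abs=1e-10)
        w1 = CureModelParams(0.0, 1.0, lam)
        assert neg_loglik(w1, times, events, "weibull") == pytest.approx(
            neg_loglik(w1, times, events, "exponential"), abs=1e-10)
        t = rng.uniform(0.1, 50)
        assert cure_survival(t, w1) == pytest.approx(np.exp(-t / lam), abs=1e-12)
        assert cure_hazard(t, w1) == pytest.approx(1 / lam, abs=1e-12)


# -------------------------------------------------------------------- fitting


def test_mle_recovers_truth_within_3se():
    cfg = SyntheticConfig(
        n=2000, pi=0.5, shape=1.5, scale=20.0,
        censoring={"kind": "administrative", "time": 60.0},
    )
    times, events = simulate_survival(cfg, seed=21)
    fit = fit_mle(times, events, "weibull_cure")
    assert fit.converged
    se = np.sqrt(np.diag(fit.cov))
    from scipy import special
    theta_true = np.array([special.logit(0.5), np.log(1.5), np.log(20.0)])
    assert np.all(np.abs(fit.theta - theta_true) < 3 * se)
    assert fit.aic == pytest.approx(2 * 3 - 2 * fit.loglik)


def test_weibull_fit_on_exponential_data_gives_shape_near_one():
    rng = np.random.default_rng(33)
    times = rng.exponential(10.0, size=2000)
    cens = np.full(2000, 40.0)
    t, e = np.minimum(times, cens), (times <= cens).astype(int)
    fit = fit_mle(t, e, "weibull")
    se_logk = np.sqrt(fit.cov[0, 0])
    assert abs(np.log(fit.params.shape)) < 2 * se_logk


def test_fit_cross_checked_against_lifelines():
    from lifelines import ExponentialFitter, WeibullFitter

    rng = np.random.default_rng(8)
    times = rng.weibull(1.6, size=500) * 15
    cens = np.full(500, 30.0)
    t, e = np.minimum(times, cens), (times <= cens).astype(int)
    ours_w = fit_mle(t, e, "weibull")
    wf = WeibullFitter().fit(t, e)
    assert ours_w.params.scale == pytest.approx(wf.lambda_, rel=1e-3)
    assert ours_w.params.shape == pytest.approx(wf.rho_, rel=1e-3)
    assert ours_w.loglik == pytest.approx(wf.log_likelihood_, abs=1e-3)
    ours_e = fit_mle(t, e, "exponential")
    ef = ExponentialFitter().fit(t, e)
    assert ours_e.params.scale == pytest.approx(ef.lambda_, rel=1e-3)


def test_duplicated_rows_same_estimate_halved_variance():
    cfg = SyntheticConfig(n=600)
    t, e = simulate_survival(cfg, seed=2)
    fit1 = fit_mle(t, e, "weibull_cure")
    fit2 = fit_mle(np.tile(t, 2), np.tile(e, 2), "weibull_cure")
    assert np.allclose(fit1.theta, fit2.theta, atol=1e-4)
    assert np.allclose(np.diag(fit2.cov), np.diag(fit1.cov) / 2, rtol=0.02)


def test_fit_invariant_to_ordering_and_time_rescaling():
    cfg = SyntheticConfig(n=400)
    t, e = simulate_survival(cfg, seed=14)
    fit = fit_mle(t, e, "weibull_cure")
    perm = np.random.default_rng(0).permutation(len(t))
    fit_perm = fit_mle(t[perm], e[perm], "weibull_cure")
    assert np.allclose(fit.theta, fit_perm.theta, atol=1e-6)
    fit_scaled = fit_mle(t * 12.0, e, "weibull_cure")
    assert fit_scaled.params.scale == pytest.approx(12 * fit.params.scale, rel=1e-3)
    assert fit_scaled.params.shape == pytest.approx(fit.params.shape, rel=1e-3)
    assert fit_scaled.params.pi == pytest.approx(fit.params.pi, abs=1e-4)


def test_fit_rejects_tiny_or_eventless_input():
    with pytest.raises(ValueError):
        fit_mle([1.0] * 5, [1] * 5, "weibull_cure")
    with pytest.raises(ValueError):
        fit_mle([1.0] * 20, [0] * 20, "weibull")


# ---------------------------------------------------------- CI and comparison


def test_cure_fraction_ci_shrinks_with_n_and_degenerates_at_level_zero():
    cfg_small = SyntheticConfig(n=189)
    cfg_big = SyntheticConfig(n=8000)
    t1, e1 = simulate_survival(cfg_small, seed=5)
    t2, e2 = simulate_survival(cfg_big, seed=5)
    f1 = fit_mle(t1, e1, "weibull_cure")
    f2 = fit_mle(t2, e2, "weibull_cure")
    _, lo1, hi1 = cure_fraction_ci(f1)
    _, lo2, hi2 = cure_fraction_ci(f2)
    assert (hi2 - lo2) < (hi1 - lo1)
    assert 0.0 < lo2 and hi2 < 1.0
    assert lo2 <= 0.51 <= hi2
    est, lo0, hi0 = cure_fraction_ci(f1, level=0.0)
    assert lo0 == est == hi0


def test_replica_scale_ci_width_comparable_to_published(replica_survival):
    """n=189, ~83 events: CI width near the published 0.17."""
    times, events = replica_survival
    fit = fit_mle(times, events, "weibull_cure")
    est, lo, hi = cure_fraction_ci(fit, times=times, events=events)
    assert 0.10 < hi - lo < 0.25
    assert 0.40 < est < 0.62


def test_model_comparison_prefers_true_model():
    cfg = SyntheticConfig(n=2000, pi=0.5, shape=1.5, scale=20.0,
                          censoring={"kind": "administrative", "time": 60.0})
    t, e = simulate_survival(cfg, seed=77)
    fits = [fit_mle(t, e, m) for m in ("exponential", "weibull", "weibull_cure")]
    ranked = model_compare_aic(fits)
    assert ranked["model"].iloc[0] == "weibull_cure"
    assert ranked["delta_aic"].iloc[0] == 0.0


def test_exponential_within_2_aic_of_weibull_on_exponential_data():
    rng = np.random.default_rng(55)
    times = rng.exponential(12.0, size=2000)
    cens = np.full(2000, 50.0)
    t, e = np.minimum(times, cens), (times <= cens).astype(int)
    fits = [fit_mle(t, e, m) for m in ("exponential", "weibull")]
    ranked = model_compare_aic(fits)
    assert ranked["delta_aic"].iloc[1] <= 2.0


def test_model_comparison_rejects_mismatched_data():
    cfg = SyntheticConfig(n=200)
    t, e = simulate_survival(cfg, seed=1)
    f1 = fit_mle(t, e, "weibull")
    f2 = fit_mle(t[:150], e[:150], "weibull")
    with pytest.raises(ValueError):
        model_compare_aic([f1, f2])


def test_gof_pairs_self_fit_and_wrong_model():
    cfg = SyntheticConfig(n=10_000, pi=0.5, shape=1.5, scale=20.0,
                          censoring={"kind": "administrative", "time": 60.0})
    t, e = simulate_survival(cfg, seed=3)
    curve = km_fit(t, e)
    good = gof_pairs(curve, fit_mle(t, e, "weibull_cure"))
    bad = gof_pairs(curve, fit_mle(t, e, "exponential"))
    assert good.attrs["max_abs_discrepancy"] < 0.03
    assert bad.attrs["max_abs_discrepancy"] > good.attrs["max_abs_discrepancy"]
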