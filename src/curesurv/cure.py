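"""Parametric survival models with a cured ("long-term survivor") fraction.

The population model is the standard two-component mixture

    S(t) = pi + (1 - pi) * S_W(t),        S_W(t) = exp(-(t/lam)^k),

where ``pi`` is the cure fraction (the survival curve's asymptote), and the
susceptible subpopulation follows a Weibull with shape ``k`` and scale
``lam`` (months).  ``pi = 0`` recovers the plain Weibull model and ``k = 1``
the exponential, so the three candidate models form a nested family; all
three are fitted by maximum likelihood to right-censored data.

The right-censored log-likelihood is

    l = sum_events log[(1 - pi) f_W(t_i)] + sum_censored log[pi + (1 - pi) S_W(t_i)]

maximized by quasi-Newton search on the unconstrained transforms
(logit pi, log k, log lam) with multiple starts (mixture likelihoods can be
multi-modal).  Standard errors come from the numerically differentiated
observed information on the transformed scale; the cure-fraction CI is a
delta-method interval on the logit scale, with a profile-likelihood
fallback when the information matrix is ill-conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .km import km_fit

logger = logging.getLogger("curesurv")

MODELS = ("exponential", "weibull", "weibull_cure")

#: optimizer defaults: objective/parameter tolerances and multi-start count
FIT_CONFIG = {
    "n_starts": 5,
    "gtol": 1e-8,
    "xtol": 1e-6,
    "jitter_sd": 0.5,
    "seed": 0,
    "min_records": 10,
}


@dataclass
class CureModelParams:
    """Natural-scale parameters: cure fraction pi, Weibull shape k, scale lam."""

    pi: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0 or self.pi == 1.0):
            raise ValueError("cure fraction must lie in [0, 1]")
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")


@dataclass
class ParametricFit:
    model: str
    params: CureModelParams
    loglik: float
    aic: float
    cov: np.ndarray | None          # on the transformed scale
    converged: bool
    n: int
    n_events: int
    theta: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict, repr=False)


# ----------------------------------------------------------- model quantities


def weibull_survival(t, shape: float, scale: float):
    t = np.asarray(t, dtype=float)
    return np.exp(-((t / scale) ** shape))


def weibull_density(t, shape: float, scale: float):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        return (shape / scale) * (t / scale) ** (shape - 1.0) * np.exp(-((t / scale) ** shape))


def cure_survival(t, params: CureModelParams):
    """Population survival pi + (1 - pi) exp(-(t/lam)^k); errors on t < 0."""
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    out = params.pi + (1.0 - params.pi) * weibull_survival(t_arr, params.shape, params.scale)
    return float(out) if np.ndim(t) == 0 else out


def cure_hazard(t, params: CureModelParams):
    """Population hazard (1 - pi) f_W(t) / S(t); decays to 0 when pi > 0."""
    t_arr = np.asarray(t, dtype=float)
    num = (1.0 - params.pi) * weibull_density(t_arr, params.shape, params.scale)
    den = params.pi + (1.0 - params.pi) * weibull_survival(t_arr, params.shape, params.scale)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return float(out) if np.ndim(t) == 0 else out


# ------------------------------------------------------------- log-likelihood


def neg_loglik(params: CureModelParams, times, events, model: str = "weibull_cure") -> float:
    """Negative right-censored log-likelihood of the (possibly degenerate) mixture.

    With pi = 0 this is exactly the plain Weibull censored likelihood, and
    with k = 1 the Weibull terms reduce to exponential terms.  An event
    recorded at t = 0 is a hard error (the density is undefined at 0 for
    shape < 1 and the likelihood degenerate otherwise).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if ((times == 0) & (events == 1)).any():
        raise ValueError("event recorded at t = 0; shift or exclude it first")
    pi, k, lam = params.pi, params.shape, params.scale
    if model == "exponential" and not np.isclose(k, 1.0):
        raise ValueError("exponential model requires shape = 1")
    if model in ("exponential", "weibull") and pi != 0.0:
        raise ValueError("non-cure models require pi = 0")

    with np.errstate(over="ignore"):
        z = (times / lam) ** k
    if not np.isfinite(z).all():
        return np.inf
    sw = np.exp(-z)
    ev = events == 1
    ll = 0.0
    if ev.any():
        log_f = np.log(k / lam) + (k - 1.0) * np.log(times[ev] / lam) - z[ev]
        ll += np.sum(np.log1p(-pi) + log_f) if pi > 0 else np.sum(log_f)
    if (~ev).any():
        s_pop = pi + (1.0 - pi) * sw[~ev]
        ll += np.sum(np.log(np.maximum(s_pop, 1e-300)))
    return -float(ll)


# ------------------------------------------------------------- transforms


def _n_params(model: str) -> int:
    return {"exponential": 1, "weibull": 2, "weibull_cure": 3}[model]


def _theta_to_params(theta: np.ndarray, model: str) -> CureModelParams:
    if model == "weibull_cure":
        return CureModelParams(float(special.expit(theta[0])), float(np.exp(theta[1])), float(np.exp(theta[2])))
    if model == "weibull":
        return CureModelParams(0.0, float(np.exp(theta[0])), float(np.exp(theta[1])))
    return CureModelParams(0.0, 1.0, float(np.exp(theta[0])))


def _params_to_theta(params: CureModelParams, model: str) -> np.ndarray:
    if model == "weibull_cure":
        return np.array([special.logit(np.clip(params.pi, 1e-6, 1 - 1e-6)),
                         np.log(params.shape), np.log(params.scale)])
    if model == "weibull":
        return np.array([np.log(params.shape), np.log(params.scale)])
    return np.array([np.log(params.scale)])


def numeric_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


# --------------------------------------------------------------------- fitting


def fit_mle(times, events, model: str = "weibull_cure", init: CureModelParams | None = None,
            config: dict | None = None) -> ParametricFit:
    """Maximum-likelihood fit of one of the three nested models.

    Multi-start quasi-Newton on the unconstrained transforms.  The base
    start is data-informed: pi from the KM plateau (last KM value), lam from
    the median event time, k = 1; remaining starts jitter these on the
    transformed scale with a seeded generator.
    """
    cfg = dict(FIT_CONFIG)
    if config:
        cfg.update(config)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, n_events = len(times), int(events.sum())
    if n < cfg["min_records"]:
        raise ValueError(f"need at least {cfg['min_records']} records, got {n}")
    if n_events == 0:
        if model != "weibull_cure":
            raise ValueError("all observations censored: non-cure models cannot be fitted")
        logger.warning("all observations censored: cure fraction at the boundary pi -> 1")

    if ((times == 0) & (events == 1)).any():
        smallest = times[times > 0].min()
        logger.warning("events at t = 0 shifted to %.6g (half the smallest positive time)", smallest / 2)
        times = np.where((times == 0) & (events == 1), smallest / 2, times)

    if init is None:
        kmc = km_fit(times, events)
        plateau = float(kmc.survival[-1]) if len(kmc.survival) else 0.99
        pi0 = float(np.clip(plateau, 0.02, 0.95))
        ev_times = times[events == 1]
        lam0 = float(np.median(ev_times)) if len(ev_times) else float(np.median(times))
        init = CureModelParams(pi0 if model == "weibull_cure" else 0.0, 1.0, max(lam0, 1e-6))
    theta0 = _params_to_theta(init, model)

    def objective(theta):
        try:
            return neg_loglik(_theta_to_params(theta, model), times, events, model)
        except (OverflowError, FloatingPointError):
            return np.inf

    rng = np.random.default_rng(cfg["seed"])
    starts = [theta0] + [
        theta0 + rng.normal(scale=cfg["jitter_sd"], size=len(theta0))
        for _ in range(cfg["n_starts"] - 1)
    ]
    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="BFGS",
                                options={"gtol": cfg["gtol"], "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta_hat = best.x
    params = _theta_to_params(theta_hat, model)
    loglik = -float(best.fun)
    dim = _n_params(model)
    H = numeric_hessian(objective, theta_hat)
    cov, spd = None, False
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() > 0:
            cov = np.linalg.inv(H)
            spd = True
    except np.linalg.LinAlgError:
        pass
    converged = bool(best.success or np.linalg.norm(best.jac, ord=np.inf) < 1e-3)
    return ParametricFit(
        model=model, params=params, loglik=loglik, aic=2 * dim - 2 * loglik,
        cov=cov, converged=converged and spd, n=n, n_events=n_events,
        theta=theta_hat,
        diagnostics={"optimizer_message": best.message, "hessian_spd": spd,
                     "grad_norm": float(np.linalg.norm(best.jac, ord=np.inf))},
    )


def cure_fraction_ci(fit: ParametricFit, level: float = 0.95,
                     times=None, events=None) -> tuple[float, float, float]:
    """Cure-fraction point estimate with a delta-method CI on the logit scale.

    Falls back to a profile-likelihood interval when the observed
    information is singular/ill-conditioned and the data are supplied.
    """
    if fit.model != "weibull_cure":
        raise ValueError("cure_fraction_ci requires a weibull_cure fit")
    if not fit.converged:
        raise ValueError("fit did not converge")
    est = fit.params.pi
    if level == 0:
        return est, est, est
    z = stats.norm.ppf(0.5 + level / 2)
    if fit.cov is not None and np.isfinite(fit.cov[0, 0]) and fit.cov[0, 0] > 0:
        theta0 = special.logit(np.clip(est, 1e-12, 1 - 1e-12))
        se = float(np.sqrt(fit.cov[0, 0]))
        lo = float(special.expit(theta0 - z * se))
        hi = float(special.expit(theta0 + z * se))
        return est, lo, hi
    if times is None or events is None:
        raise ValueError("singular covariance and no data supplied for profile CI")
    return (est, *profile_ci_pi(times, events, fit, level))


def profile_ci_pi(times, events, fit: ParametricFit, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for pi by grid inversion of the LR statistic."""
    crit = stats.chi2.ppf(level, df=1) / 2.0
    grid = np.linspace(0.005, 0.995, 199)
    lmax = fit.loglik
    ok = []
    for pi in grid:
        def obj(th):
            p = CureModelParams(pi, float(np.exp(th[0])), float(np.exp(th[1])))
            return neg_loglik(p, times, events, "weibull_cure")
        res = optimize.minimize(obj, fit.theta[1:], method="Nelder-Mead")
        if lmax + res.fun <= crit:
            ok.append(pi)
    if not ok:
        return fit.params.pi, fit.params.pi
    return float(min(ok)), float(max(ok))


def model_compare_aic(fits: list[ParametricFit]) -> pd.DataFrame:
    """AIC ranking (ascending) of fits on the same data, with delta-AIC."""
    if not fits:
        raise ValueError("no fits supplied")
    ns = {(f.n, f.n_events) for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are not on identical data: n/n_events {sorted(ns)}")
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
            "converged": [f.converged for f in fits],
        }
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def gof_pairs(km_curve, fit: ParametricFit) -> pd.DataFrame:
    """KM vs model survival at the KM event times (overlay / QQ-style pairs).

    The returned frame carries ``attrs['max_abs_discrepancy']``.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    t = km_curve.event_times
    df = pd.DataFrame(
        {
            "t": t,
            "S_km": km_curve.survival,
            "S_model": cure_survival(t, fit.params) if len(t) else np.array([]),
        }
    )
    df.attrs["max_abs_discrepancy"] = (
        float(np.max(np.abs(df["S_km"] - df["S_model"]))) if len(df) else float("nan")
    )
    return df
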