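"""Nonparametric survival: Kaplan-Meier, reverse-KM follow-up, smoothed hazard.

The product-limit estimator is implemented directly because its internals
(at-risk bookkeeping, Greenwood variance, Nelson-Aalen increments) feed the
parametric goodness-of-fit overlays and the kernel-smoothed hazard; tests
cross-check it against an independent survival library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("curesurv")


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``event_times`` are the distinct times with >= 1 death; ``survival`` is
    the estimate just after each, with Greenwood variance attached.  Ties
    between deaths and censorings at the same time are resolved with deaths
    first (the censored subject is still at risk at the death time).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray
    variance: np.ndarray
    n: int

    def median(self) -> float:
        """Smallest time with S(t) <= 0.5; NaN if the curve never crosses."""
        below = self.survival <= 0.5
        if not below.any():
            return float("nan")
        return float(self.event_times[np.argmax(below)])


@dataclass
class HazardCurve:
    grid: np.ndarray
    hazard: np.ndarray
    bandwidth: float


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if len(times) == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative survival time")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    uniq = np.unique(times[events == 1])
    surv, var_terms, at_risk, n_events = [], [], [], []
    s = 1.0
    greenwood = 0.0
    for t in uniq:
        # deaths precede censorings at tied times: at risk = all with time >= t
        r = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / r
        if r > d:
            greenwood += d / (r * (r - d))
        at_risk.append(r)
        n_events.append(d)
        surv.append(s)
        var_terms.append(s * s * greenwood if s > 0 else 0.0)
    return KMCurve(
        event_times=uniq,
        survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int),
        n_events=np.array(n_events, dtype=int),
        censor_times=np.sort(times[events == 0]),
        variance=np.array(var_terms),
        n=n,
    )


def km_eval(curve: KMCurve, t) -> np.ndarray | float:
    """Right-continuous step-function value S(t); S = 1 before the first event."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t must be nonnegative")
    idx = np.searchsorted(curve.event_times, t_arr, side="right")
    vals = np.concatenate([[1.0], curve.survival])[idx]
    return float(vals[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else vals


def km_confidence_band(curve: KMCurve, level: float = 0.95, log_log: bool = False):
    """Pointwise CI: plain Greenwood by default, log-log on request."""
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(curve.variance)
    s = curve.survival
    if not log_log:
        lo, hi = np.clip(s - z * se, 0, 1), np.clip(s + z * se, 0, 1)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where((s > 0) & (s < 1), np.log(-np.log(np.clip(s, 1e-300, 1))), np.nan)
            se_theta = np.where(s > 0, se / np.abs(s * np.log(np.clip(s, 1e-300, 1))), np.nan)
            lo = np.exp(-np.exp(theta + z * se_theta))
            hi = np.exp(-np.exp(theta - z * se_theta))
            lo, hi = np.where(np.isnan(lo), s, lo), np.where(np.isnan(hi), s, hi)
    return lo, hi


def median_followup_reverse_km(times, events) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event of interest (indicators inverted) and
    the KM median of that censoring distribution is returned.  NaN with a
    logged warning if the censoring survival never reaches 0.5 or there are
    no censored records.
    """
    events = np.asarray(events, dtype=int)
    if (events == 0).sum() == 0:
        logger.warning("reverse KM undefined: no censored observations")
        return float("nan")
    rev = km_fit(times, 1 - events)
    med = rev.median()
    if np.isnan(med):
        logger.warning("reverse KM: censoring survival never crosses 0.5")
    return med


def naive_median_followup(times, events) -> float:
    """Plain median of the censored subjects' follow-up times (comparison only)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    cens = times[events == 0]
    return float(np.median(cens)) if len(cens) else float("nan")


def smoothed_hazard(curve: KMCurve, bandwidth: float = 3.0, grid=None) -> HazardCurve:
    """Kernel-smoothed empirical hazard from Nelson-Aalen increments.

    Epanechnikov kernel over the discrete hazard increments d_i/n_i, with
    reflection about t = 0 as boundary correction so mass near the origin is
    not lost.  Grid points beyond the observed range get 0 with a warning.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        upper = curve.event_times.max() if len(curve.event_times) else 1.0
        grid = np.linspace(0.0, float(upper), 200)
    grid = np.asarray(grid, dtype=float)
    if len(curve.event_times) == 0:
        return HazardCurve(grid, np.zeros_like(grid), bandwidth)

    t_max = max(curve.event_times.max(), curve.censor_times.max() if len(curve.censor_times) else 0)
    if (grid > t_max + bandwidth).any():
        logger.warning("smoothed_hazard: grid extends beyond observed range; zeros there")

    increments = curve.n_events / curve.at_risk       # Nelson-Aalen jumps
    u = (grid[:, None] - curve.event_times[None, :]) / bandwidth
    u_reflect = (grid[:, None] + curve.event_times[None, :]) / bandwidth
    kern = _epanechnikov(u) + _epanechnikov(u_reflect)   # reflection at 0
    hazard = (kern * increments[None, :]).sum(axis=1) / bandwidth
    return HazardCurve(grid, np.maximum(hazard, 0.0), bandwidth)


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)


def nelson_aalen_total(curve: KMCurve) -> float:
    """Total Nelson-Aalen mass (cumulative hazard at the last event time)."""
    return float((curve.n_events / curve.at_risk).sum())
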