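"""Covariate regression in the Weibull mixture-cure model.

Covariates can act on the cure probability through a logistic link,
logit(pi_i) = x_i' b_pi, and/or on the Weibull scale through a log link,
log(lam_i) = lam0-free x_i' b_lam, with a single shape k shared across
subjects.  With an intercept-only design the model reduces exactly to the
plain mixture-cure fit of :mod:`curesurv.cure`.

Estimation is maximum likelihood on the joint parameter vector
(b_pi, b_lam, log k) by quasi-Newton search; Wald standard errors, CIs and
p-values come from the numerically differentiated observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import Cohort, marker_calls, stage_groups, MARKER_COLUMNS
from .cure import CureModelParams, fit_mle, numeric_hessian

logger = logging.getLogger("curesurv")

LINKS = ("cure_fraction", "scale")


@dataclass
class Covariate:
    name: str
    kind: str                     # binary | categorical | continuous
    reference: str | None = None  # reference level for categoricals
    standardize: bool = False     # continuous only


@dataclass
class DesignSpec:
    covariates: list[Covariate]
    links: tuple[str, ...] = ("cure_fraction", "scale")

    def __post_init__(self) -> None:
        if not self.links or any(l not in LINKS for l in self.links):
            raise ValueError(f"links must be a nonempty subset of {LINKS}")


@dataclass
class CureRegressionFit:
    coefficients: pd.DataFrame    # term, link, estimate, se, ci_low, ci_high, p
    shape: float
    loglik: float
    aic: float
    converged: bool
    n: int
    n_events: int
    links: tuple[str, ...]
    design_columns: list[str] = field(default_factory=list, repr=False)
    cov: np.ndarray | None = field(default=None, repr=False)
    theta: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------- design


def _covariate_series(cohort: Cohort, name: str) -> pd.Series:
    if name == "stage_group":
        return stage_groups(cohort)
    if name in MARKER_COLUMNS:
        return marker_calls(cohort, name)
    return cohort.df[name]


def build_design(cohort: Cohort, spec: DesignSpec):
    """Design matrix (with intercept) + aligned responses.

    Treatment coding against each categorical's reference level; records
    with any missing covariate, time or event are dropped with a logged
    count.  Collinear columns are a hard error naming the offenders.
    """
    df = cohort.df
    seen = [c.name for c in spec.covariates]
    dups = sorted({nm for nm in seen if seen.count(nm) > 1})
    if dups:
        raise ValueError(f"collinear design columns: duplicated covariate(s) {dups}")
    cols: dict[str, pd.Series] = {}
    for cov in spec.covariates:
        s = _covariate_series(cohort, cov.name)
        if cov.kind == "continuous":
            s = pd.to_numeric(s, errors="coerce")
            cols[cov.name] = s
        elif cov.kind == "binary":
            s = pd.to_numeric(s, errors="coerce")
            cols[cov.name] = s
        elif cov.kind == "categorical":
            levels = [lv for lv in pd.unique(s.dropna())]
            ref = cov.reference if cov.reference is not None else sorted(levels)[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent for covariate {cov.name!r}")
            for lv in sorted(lv for lv in levels if lv != ref):
                cols[f"{cov.name}[{lv}]"] = (s == lv).astype(float).where(~s.isna())
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")

    design = pd.DataFrame(cols, index=df.index)
    keep = ~(design.isna().any(axis=1) | df["time_months"].isna() | df["event"].isna())
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_design: dropped %d record(s) with missing covariates", dropped)
    design = design.loc[keep].astype(float)

    for cov in spec.covariates:
        if cov.kind == "continuous" and cov.standardize:
            v = design[cov.name]
            design[cov.name] = (v - v.mean()) / v.std(ddof=0)

    X = np.column_stack([np.ones(len(design)), design.to_numpy()])
    names = ["intercept"] + list(design.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the dependency via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"collinear design columns: {bad or names}")
    times = df.loc[keep, "time_months"].to_numpy(dtype=float)
    events = df.loc[keep, "event"].to_numpy(dtype=int)
    return X, names, times, events


# ---------------------------------------------------------------- likelihood


def _unpack(theta: np.ndarray, p: int, links) -> tuple[np.ndarray | None, np.ndarray | None, float]:
    i = 0
    b_pi = b_lam = None
    if "cure_fraction" in links:
        b_pi = theta[i:i + p]; i += p
    if "scale" in links:
        b_lam = theta[i:i + p]; i += p
    log_k = theta[i]
    return b_pi, b_lam, float(log_k)


def neg_loglik_regression(theta, X, times, events, links, base_pi, base_log_lam) -> float:
    """Negative log-likelihood of the covariate mixture-cure model.

    Links without covariates use a single free intercept held in ``theta``
    anyway (the design always contains an intercept column), so ``base_*``
    are only offsets of zero kept for clarity of the parameterization.
    """
    p = X.shape[1]
    b_pi, b_lam, log_k = _unpack(np.asarray(theta, dtype=float), p, links)
    k = np.exp(log_k)
    eta_pi = X @ b_pi if b_pi is not None else np.full(len(times), base_pi)
    eta_lam = X @ b_lam if b_lam is not None else np.full(len(times), base_log_lam)
    pi = special.expit(eta_pi)
    lam = np.exp(eta_lam)
    with np.errstate(over="ignore"):
        z = (times / lam) ** k
    if not np.isfinite(z).all():
        return np.inf
    ev = events == 1
    ll = 0.0
    if ev.any():
        log_f = np.log(k / lam[ev]) + (k - 1.0) * np.log(times[ev] / lam[ev]) - z[ev]
        ll += float(np.sum(np.log1p(-pi[ev]) + log_f))
    if (~ev).any():
        s_pop = pi[~ev] + (1.0 - pi[~ev]) * np.exp(-z[~ev])
        ll += float(np.sum(np.log(np.maximum(s_pop, 1e-300))))
    return -ll


def fit_cure_regression(X, names, times, events, links=("cure_fraction", "scale"),
                        config: dict | None = None) -> CureRegressionFit:
    """Fit the covariate mixture-cure model by maximum likelihood.

    Initialization: intercepts from the intercept-only mixture-cure fit,
    covariate coefficients at zero.  Separation in the cure part (a
    covariate level with no events) is logged as a warning; Wald inference
    is still reported but should be read with care there.
    """
    cfg = {"gtol": 1e-8, "maxiter": 2000}
    if config:
        cfg.update(config)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=float)
    if events.sum() == 0:
        raise ValueError("no events: regression cannot be fitted")
    _warn_separation(X, names, events)

    base = fit_mle(times, events, "weibull_cure")
    p = X.shape[1]
    theta0 = []
    if "cure_fraction" in links:
        theta0 += [special.logit(np.clip(base.params.pi, 1e-4, 1 - 1e-4))] + [0.0] * (p - 1)
    if "scale" in links:
        theta0 += [np.log(base.params.scale)] + [0.0] * (p - 1)
    theta0.append(np.log(base.params.shape))
    theta0 = np.array(theta0)

    base_pi = special.logit(np.clip(base.params.pi, 1e-4, 1 - 1e-4))
    base_log_lam = np.log(base.params.scale)

    def obj(th):
        return neg_loglik_regression(th, X, times, events, links, base_pi, base_log_lam)

    res = optimize.minimize(obj, theta0, method="BFGS",
                            options={"gtol": cfg["gtol"], "maxiter": cfg["maxiter"]})
    theta_hat = res.x
    loglik = -float(res.fun)
    H = numeric_hessian(obj, theta_hat)
    cov = None
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() > 0:
            cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass
    converged = bool((res.success or np.linalg.norm(res.jac, ord=np.inf) < 1e-3) and cov is not None)
    if not converged:
        logger.warning("cure regression did not fully converge: %s", res.message)

    se = np.sqrt(np.diag(cov)) if cov is not None else np.full(len(theta_hat), np.nan)
    z = stats.norm.ppf(0.975)
    terms, link_col = [], []
    if "cure_fraction" in links:
        terms += names; link_col += ["cure_fraction:logit"] * p
    if "scale" in links:
        terms += names; link_col += ["scale:log"] * p
    terms.append("log_shape"); link_col.append("shape")
    est = theta_hat
    zval = est / se
    coef = pd.DataFrame(
        {
            "term": terms,
            "link": link_col,
            "estimate": est,
            "se": se,
            "ci_low": est - z * se,
            "ci_high": est + z * se,
            "p": 2 * stats.norm.sf(np.abs(zval)),
        }
    )
    dim = len(theta_hat)
    return CureRegressionFit(
        coefficients=coef, shape=float(np.exp(theta_hat[-1])), loglik=loglik,
        aic=2 * dim - 2 * loglik, converged=converged, n=len(times),
        n_events=int(events.sum()), links=tuple(links), design_columns=list(names),
        cov=cov, theta=theta_hat,
    )


def _warn_separation(X, names, events) -> None:
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            for level, mask in ((1, col == 1), (0, col == 0)):
                if mask.any() and events[mask].sum() == 0:
                    logger.warning(
                        "possible separation: no events at %s = %d; Wald CIs may be unstable",
                        names[j], level,
                    )


def summarize_fit(fit: CureRegressionFit) -> pd.DataFrame:
    """Forest-style summary table (one row per term per linked parameter)."""
    out = fit.coefficients.copy()
    out["significant"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    if not fit.converged:
        logger.warning("summarize_fit: fit flagged non-converged; interpret with caution")
        out.attrs["warning"] = "fit did not converge"
    return out


def forest_plot(fit: CureRegressionFit, path) -> None:
    """Render the coefficient table as a forest plot (headless-safe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coef = fit.coefficients[fit.coefficients["term"] != "log_shape"]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(coef) + 1.5))
    y = np.arange(len(coef))[::-1]
    ax.errorbar(coef["estimate"], y,
                xerr=[coef["estimate"] - coef["ci_low"], coef["ci_high"] - coef["estimate"]],
                fmt="o", color="black", capsize=2)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(coef["link"] + " " + coef["term"])
    ax.set_xlabel("coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
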