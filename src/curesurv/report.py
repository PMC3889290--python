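"""End-to-end pipeline orchestration and reproducible report bundles.

Two entry points mirror the two halves of the analysis:

* :func:`run_concordance_report` — pairwise marker agreement (kappa +
  McNemar) over all informative marker pairs, positivity-by-stage tables,
  and the marker-by-covariate chi-square battery;
* :func:`run_survival_report` — postoperative-death exclusion, KM curve,
  the three parametric fits with AIC ranking, KM-vs-model overlay and
  QQ-style pairs, parametric and kernel-smoothed hazard curves, the
  cure-fraction CI, and the covariate cure regression.

Every bundle carries a manifest (config, seed, input digests, output
inventory with digests) so a rerun with identical inputs is byte-checkable.
TSV/JSON files are the contract; plots are an optional convenience.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort, INFORMATIVE_MARKERS, exclude_postoperative_deaths, read_cohort,
)
from .concordance import (
    association_battery, format_p, pair_agreement, positivity_by_stage,
    stage_association_table, pearson_chi_square,
)
from .cure import cure_fraction_ci, cure_hazard, fit_mle, gof_pairs, model_compare_aic
from .km import km_fit, median_followup_reverse_km, smoothed_hazard
from .regression import Covariate, DesignSpec, build_design, fit_cure_regression, summarize_fit

logger = logging.getLogger("curesurv")

DEFAULT_CONFIG = {
    "markers": list(INFORMATIVE_MARKERS),
    "association_covariates": ["age", "lauren", "pt", "pn", "stage_group"],
    "hazard_bandwidth_months": 3.0,
    "ci_level": 0.95,
    "regression_links": ["cure_fraction", "scale"],
    "regression_covariates": [
        {"name": "age", "kind": "continuous", "standardize": True},
        {"name": "radicality", "kind": "categorical", "reference": "R0"},
        {"name": "location", "kind": "categorical", "reference": "stomach"},
        {"name": "lauren", "kind": "categorical", "reference": "intestinal"},
        {"name": "adjuvant", "kind": "categorical", "reference": "surgery_alone"},
        {"name": "stage_group", "kind": "categorical", "reference": "0_I_II"},
        {"name": "her2_membrane", "kind": "binary"},
        {"name": "her3_cytoplasm", "kind": "binary"},
    ],
    "seed": 0,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _resolve(cohort_or_path) -> tuple[Cohort, dict]:
    if isinstance(cohort_or_path, Cohort):
        return cohort_or_path, {"source": cohort_or_path.provenance}
    path = Path(cohort_or_path)
    return read_cohort(path), {"source": str(path), "sha256": _sha256(path)}


def _write_manifest(outdir: Path, stage: str, config: dict, inputs: dict) -> None:
    inventory = {
        f.name: _sha256(f)
        for f in sorted(outdir.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": {k: v for k, v in config.items()},
        "inputs": inputs,
        "outputs": inventory,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_concordance_report(cohort_or_path, outdir, config: dict | None = None) -> dict:
    """Pairwise agreement + positivity + association battery report bundle."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    cohort, inputs = _resolve(cohort_or_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    markers = cfg["markers"]
    if len(markers) < 2:
        logger.warning("fewer than two markers: pairwise section empty")
    pair_rows, pair_json = [], {}
    for a, b in itertools.combinations(markers, 2):
        res = pair_agreement(cohort, a, b)
        t = res.table.counts
        pair_rows.append({
            "marker_a": a, "marker_b": b,
            "pos_pos": t[0, 0], "pos_neg": t[0, 1], "neg_pos": t[1, 0], "neg_neg": t[1, 1],
            "n": res.n, "kappa": round(res.kappa, 3),
            "mcnemar_stat": round(res.mcnemar_stat, 3), "mcnemar_p": format_p(res.mcnemar_p),
        })
        pair_json[f"{a}|{b}"] = {
            "counts": t.tolist(), "n": res.n, "kappa": res.kappa,
            "mcnemar_stat": res.mcnemar_stat, "mcnemar_p": res.mcnemar_p,
            "degenerate": res.degenerate,
        }
    pd.DataFrame(pair_rows).to_csv(outdir / "pairwise_agreement.tsv", sep="\t", index=False)
    (outdir / "pairwise_agreement.json").write_text(json.dumps(pair_json, indent=2) + "\n")

    pos_rows = []
    for m in markers:
        pos = positivity_by_stage(cohort, m)
        stat, dfree, p = pearson_chi_square(stage_association_table(cohort, m))
        for _, r in pos.iterrows():
            pos_rows.append({
                "marker": m, **r.to_dict(),
                "chi2_stat": round(stat, 3), "df": dfree, "p": format_p(p),
            })
    pd.DataFrame(pos_rows).to_csv(outdir / "positivity_by_stage.tsv", sep="\t", index=False)

    battery = {}
    for m in markers:
        entries = association_battery(cohort, m, cfg["association_covariates"])
        battery[m] = [
            {k: v for k, v in e.items() if k != "table"} | {"counts": e["table"].counts.tolist()}
            for e in entries
        ]
    (outdir / "association_battery.json").write_text(
        json.dumps(battery, indent=2, default=float) + "\n")

    _write_manifest(outdir, "concordance", cfg, inputs)
    return {"outdir": str(outdir), "n_pairs": len(pair_rows)}


def run_survival_report(cohort_or_path, outdir, config: dict | None = None,
                        plots: bool = False) -> dict:
    """Survival analysis report bundle (see module docstring)."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    cohort, inputs = _resolve(cohort_or_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    analyzed = exclude_postoperative_deaths(cohort)
    times = analyzed.df["time_months"].to_numpy(dtype=float)
    events = analyzed.df["event"].to_numpy(dtype=int)
    if events.sum() == 0:
        logger.warning("no events after exclusions; only the cure model boundary applies")

    kmc = km_fit(times, events)
    pd.DataFrame({
        "time": kmc.event_times, "at_risk": kmc.at_risk, "events": kmc.n_events,
        "survival": kmc.survival, "variance": kmc.variance,
    }).to_csv(outdir / "km_curve.tsv", sep="\t", index=False)

    fits = {}
    for model in ("exponential", "weibull", "weibull_cure"):
        try:
            fits[model] = fit_mle(times, events, model, config={"seed": cfg["seed"]})
        except ValueError as exc:
            logger.warning("%s fit failed: %s", model, exc)
    ranking = model_compare_aic(list(fits.values()))
    ranking.to_csv(outdir / "aic_ranking.tsv", sep="\t", index=False)

    summary: dict = {
        "n_total": cohort.n,
        "n_analyzed": analyzed.n,
        "n_excluded_postop": cohort.n - analyzed.n,
        "n_events": int(events.sum()),
        "n_censored": int((events == 0).sum()),
        "median_followup_months": median_followup_reverse_km(times, events),
        "models": {},
    }
    for model, fit in fits.items():
        entry = {
            "params": {"pi": fit.params.pi, "shape": fit.params.shape, "scale": fit.params.scale},
            "loglik": fit.loglik, "aic": fit.aic, "converged": fit.converged,
        }
        if model == "weibull_cure" and fit.converged:
            est, lo, hi = cure_fraction_ci(fit, cfg["ci_level"], times, events)
            entry["cure_fraction"] = {"estimate": est, "ci_low": lo, "ci_high": hi,
                                      "level": cfg["ci_level"]}
        summary["models"][model] = entry
        pairs = gof_pairs(kmc, fit) if fit.converged else pd.DataFrame()
        pairs.to_csv(outdir / f"gof_pairs_{model}.tsv", sep="\t", index=False)

    grid = np.linspace(0.0, float(times.max()), 200)
    hz = smoothed_hazard(kmc, cfg["hazard_bandwidth_months"], grid)
    hz_frame = pd.DataFrame({"time": grid, "smoothed_hazard": hz.hazard})
    if "weibull_cure" in fits:
        hz_frame["cure_model_hazard"] = cure_hazard(grid, fits["weibull_cure"].params)
    hz_frame.to_csv(outdir / "hazard_curves.tsv", sep="\t", index=False)

    spec = DesignSpec(
        covariates=[Covariate(**c) for c in cfg["regression_covariates"]],
        links=tuple(cfg["regression_links"]),
    )
    try:
        X, names, rtimes, revents = build_design(analyzed, spec)
        reg = fit_cure_regression(X, names, rtimes, revents, links=spec.links)
        summarize_fit(reg).to_csv(outdir / "regression_forest.tsv", sep="\t", index=False)
        summary["regression"] = {
            "n": reg.n, "n_events": reg.n_events, "converged": reg.converged,
            "loglik": reg.loglik, "aic": reg.aic, "links": list(reg.links),
        }
        if plots:
            from .regression import forest_plot
            forest_plot(reg, outdir / "regression_forest.png")
    except ValueError as exc:
        logger.warning("cure regression skipped: %s", exc)
        summary["regression"] = {"error": str(exc)}

    (outdir / "survival_summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n")

    if plots:
        _overlay_plot(kmc, fits, outdir / "km_overlay.png")
    _write_manifest(outdir, "survival", cfg, inputs)
    return summary


def _overlay_plot(kmc, fits, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .cure import cure_survival

    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.concatenate([[0.0], np.repeat(kmc.event_times, 2)])
    s = np.concatenate([[1.0, 1.0], np.repeat(kmc.survival, 2)[:-1]])
    ax.plot(t, s, color="black", label="Kaplan-Meier")
    grid = np.linspace(0, kmc.event_times.max() if len(kmc.event_times) else 1, 200)
    for model, fit in fits.items():
        ax.plot(grid, cure_survival(grid, fit.params), label=model)
    ax.set_xlabel("months since surgery")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
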