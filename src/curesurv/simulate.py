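"""Synthetic cohort generation with the statistical structure of the study.

Three layers:

* correlated binary IHC markers — marginal positivity rates and pairwise
  Cohen kappas are prescribed; the joint 2x2 law for a pair is obtained by
  inverting the kappa formula (:func:`solve_joint_2x2`) and markers are
  drawn by a sequential conditional (chain) construction anchored on
  membrane HER2, so pairwise targets against the anchor hold exactly in
  expectation while higher-order structure is left unspecified;
* cure-mixture survival — each subject is cured with probability
  pi_i = expit(logit(pi0) + x_i' beta_pi); susceptible event times are
  Weibull with scale lam_i = lam0 * exp(x_i' beta_scale); censoring follows
  uniform accrual with an administrative cutoff (or a fixed administrative
  time, or an exponential rate);
* :func:`study_replica_cohort` — a deterministic 201-record replica whose
  categorical marginals, per-marker denominators and positives-per-stage-
  group match the published summary tables exactly, with 12 postoperative
  deaths flagged and survival drawn from the calibrated cure model
  (cure fraction 0.51; Weibull shape 1.4, scale 14 months; censoring
  uniform on 12.3-48.3 months, i.e. 36 months of accrual before a cutoff
  chosen so the reverse-KM median follow-up is ~30 months and ~83 of the
  189 analyzed patients die).

All randomness flows from a single seeded generator per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import reference_data as ref
from .cohort import Cohort, ALL_COLUMNS, MARKER_COLUMNS
from .concordance import cohen_kappa

logger = logging.getLogger("curesurv")

ANCHOR_MARKER = "her2_membrane"

#: survival calibration frozen from the study conditions (see module docstring)
DEFAULT_PI = 0.51
DEFAULT_SHAPE = 1.4
DEFAULT_SCALE = 14.0
DEFAULT_ACCRUAL_MONTHS = 36.0
DEFAULT_CUTOFF_MONTHS = 48.3


@dataclass
class SyntheticConfig:
    """Full generative specification for a synthetic cohort."""

    n: int = 189
    pi: float = DEFAULT_PI
    shape: float = DEFAULT_SHAPE
    scale: float = DEFAULT_SCALE
    beta_pi: np.ndarray | None = None
    beta_scale: np.ndarray | None = None
    #: one of {"kind": "accrual_uniform", "accrual_months": a, "cutoff_months": c},
    #: {"kind": "administrative", "time": t}, {"kind": "rate", "rate": r}
    censoring: dict = field(default_factory=lambda: {
        "kind": "accrual_uniform",
        "accrual_months": DEFAULT_ACCRUAL_MONTHS,
        "cutoff_months": DEFAULT_CUTOFF_MONTHS,
    })
    #: marker -> marginal positive rate
    markers: dict = field(default_factory=lambda: {
        m: ref.MARKER_POSITIVES[m] / ref.MARKER_DENOMINATORS[m] for m in MARKER_COLUMNS
    })
    #: (marker_a, marker_b) -> target kappa; pairs involving the anchor drive
    #: the chain construction, the rest are validated for feasibility only
    kappa_targets: dict = field(default_factory=lambda: {
        (p.marker_a, p.marker_b): p.kappa
        for p in ref.PAIRWISE_TABLES if p.verifiable
    })
    #: marker -> (n 2+, n 3+) split of positives (negatives split evenly 0 / 1+)
    ordinal_split: dict = field(default_factory=lambda: dict(ref.ORDINAL_SPLITS))
    #: marker -> probability a score is missing
    missingness: dict = field(default_factory=lambda: {
        m: 1.0 - ref.MARKER_DENOMINATORS[m] / ref.N_TOTAL for m in MARKER_COLUMNS
    })
    stage_distribution: dict = field(default_factory=lambda: {
        lv: c / ref.N_TOTAL for lv, c in ref.COHORT_MARGINALS["stage"]
    })
    seed: int = 0

    def validate(self) -> None:
        for m, p in self.markers.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal rate for {m} outside [0,1]")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("cure fraction outside [0,1]")
        for (a, b), kap in self.kappa_targets.items():
            if a in self.markers and b in self.markers:
                solve_joint_2x2(self.markers[a], self.markers[b], kap)


# ------------------------------------------------------------ kappa inversion


def kappa_feasible_range(p1: float, p2: float) -> tuple[float, float]:
    """Range of kappas attainable for two Bernoulli margins (Frechet bounds)."""
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e >= 1.0:
        return 0.0, 0.0
    p11_lo, p11_hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    def kap(p11):
        p_o = 1.0 - p1 - p2 + 2.0 * p11
        return (p_o - p_e) / (1.0 - p_e)
    return kap(p11_lo), kap(p11_hi)


def solve_joint_2x2(p1: float, p2: float, kappa: float) -> tuple[float, float, float, float]:
    """Invert the kappa formula: cell probabilities (p11, p10, p01, p00).

    Uses p_o = p_e + kappa (1 - p_e) and p11 = (p_o - 1 + p1 + p2) / 2.
    Infeasible targets raise with the attainable kappa range.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} outside [0,1]")
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    p_o = p_e + kappa * (1.0 - p_e)
    p11 = (p_o - 1.0 + p1 + p2) / 2.0
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if p11 < lo - 1e-12 or p11 > hi + 1e-12:
        klo, khi = kappa_feasible_range(p1, p2)
        raise ValueError(
            f"kappa {kappa} infeasible for margins ({p1}, {p2}); feasible range "
            f"[{klo:.4f}, {khi:.4f}]"
        )
    p11 = float(np.clip(p11, lo, hi))
    p10, p01 = p1 - p11, p2 - p11
    p00 = 1.0 - p11 - p10 - p01
    return p11, float(p10), float(p01), float(p00)


# -------------------------------------------------------------- marker layer


def simulate_markers(config: SyntheticConfig, seed: int | None = None,
                     n: int | None = None) -> pd.DataFrame:
    """Draw correlated binary calls + ordinal scores for every marker.

    Chain construction: the anchor (membrane HER2) is drawn from its
    marginal; every other marker is drawn conditionally on the anchor from
    the pair's solved joint law, so its marginal and its kappa against the
    anchor are honored.  Ordinal scores split positives into 2+/3+ and
    negatives into 0/1+ per config; per-marker missingness is applied last.

    Returns a frame with ``<marker>`` (ordinal, NaN = missing) and
    ``<marker>_call`` (binary, NaN = missing) columns.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n if n is None else n
    markers = dict(config.markers)
    if ANCHOR_MARKER not in markers:
        raise ValueError(f"anchor marker {ANCHOR_MARKER} absent from config")
    p_anchor = markers[ANCHOR_MARKER]
    calls = {ANCHOR_MARKER: (rng.random(n) < p_anchor).astype(float)}

    def target_kappa(m):
        for key in ((m, ANCHOR_MARKER), (ANCHOR_MARKER, m)):
            if key in config.kappa_targets:
                return config.kappa_targets[key]
        return 0.0

    for m, p_m in markers.items():
        if m == ANCHOR_MARKER:
            continue
        kap = target_kappa(m)
        p11, p10, p01, p00 = solve_joint_2x2(p_m, p_anchor, kap)
        p_given_pos = p11 / p_anchor if p_anchor > 0 else p_m
        p_given_neg = p10 / (1 - p_anchor) if p_anchor < 1 else p_m
        anchor = calls[ANCHOR_MARKER]
        prob = np.where(anchor == 1, p_given_pos, p_given_neg)
        calls[m] = (rng.random(n) < prob).astype(float)

    out = pd.DataFrame(index=range(n))
    for m, call in calls.items():
        n2, n3 = config.ordinal_split.get(m, (1, 1))
        frac3 = n3 / (n2 + n3) if (n2 + n3) else 0.5
        score = np.where(call == 1,
                         np.where(rng.random(n) < frac3, 3.0, 2.0),
                         np.where(rng.random(n) < 0.5, 1.0, 0.0))
        miss = rng.random(n) < config.missingness.get(m, 0.0)
        score = np.where(miss, np.nan, score)
        out[m] = score
        out[m + "_call"] = np.where(miss, np.nan, call)
    return out


# ------------------------------------------------------------ survival layer


def draw_censoring(config: SyntheticConfig, n: int, rng) -> np.ndarray:
    c = config.censoring
    kind = c.get("kind", "accrual_uniform")
    if kind == "accrual_uniform":
        lo = c["cutoff_months"] - c["accrual_months"]
        return rng.uniform(lo, c["cutoff_months"], size=n)
    if kind == "administrative":
        return np.full(n, float(c["time"]))
    if kind == "rate":
        return rng.exponential(1.0 / c["rate"], size=n)
    raise ValueError(f"unknown censoring scheme {kind!r}")


def simulate_survival(config: SyntheticConfig, covariates: np.ndarray | None = None,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw (times, events) from the covariate cure-mixture model.

    Each subject is cured with probability expit(logit(pi0) + x'beta_pi);
    susceptible subjects get a Weibull(shape, scale * exp(x'beta_scale))
    event time.  Observed time is min(event, censoring); cured subjects can
    only be censored.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n if covariates is None else len(covariates)
    eta_pi = np.full(n, special.logit(np.clip(config.pi, 1e-12, 1 - 1e-12)))
    log_scale = np.full(n, np.log(config.scale))
    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if config.beta_pi is not None:
            eta_pi = eta_pi + X @ np.asarray(config.beta_pi, dtype=float)
        if config.beta_scale is not None:
            log_scale = log_scale + X @ np.asarray(config.beta_scale, dtype=float)
    pi_i = special.expit(eta_pi)
    cured = rng.random(n) < pi_i
    event_time = np.full(n, np.inf)
    sus = ~cured
    event_time[sus] = rng.weibull(config.shape, size=int(sus.sum())) * np.exp(log_scale[sus])
    cens_time = draw_censoring(config, n, rng)
    times = np.minimum(event_time, cens_time)
    events = (event_time <= cens_time).astype(int)
    return times, events


def simulate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Generic synthetic cohort: stage + age + markers + cure-model survival."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n
    stages = list(config.stage_distribution)
    probs = np.array([config.stage_distribution[s] for s in stages], dtype=float)
    probs = probs / probs.sum()
    stage = rng.choice(stages, size=n, p=probs)
    markers = simulate_markers(config, seed=rng.integers(2**31 - 1), n=n)
    times, events = simulate_survival(config, seed=rng.integers(2**31 - 1))

    df = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "age": np.clip(np.round(rng.normal(62, 12, size=n)), 27, 88),
        "stage": pd.array(stage, dtype="string"),
        "time_months": times,
        "event": pd.array(events, dtype="Int64"),
        "postop_death": pd.array([0] * n, dtype="Int64"),
    })
    for col in MARKER_COLUMNS:
        df[col] = markers[col].to_numpy()
    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.array([pd.NA] * n, dtype="string")
    return Cohort(df[list(ALL_COLUMNS)], provenance=f"simulate_cohort(seed={seed})")


# -------------------------------------------------------------- study replica

#: stage-group row blocks of the 201-record replica (rows ordered by stage)
_G1 = slice(0, 75)       # stages 0/IA/IB/II
_G2 = slice(75, 168)     # IIIA/IIIB/IVM0
_G3 = slice(168, 198)    # IVM1
_GMISS = slice(198, 201) # stage missing

#: rows with missing scores, chosen inside the groups whose published
#: denominators fall short (HER1: 3 in group 1; HER3: 1 in group 2;
#: HER4: 2 in group 1)
_MISSING_ROWS = {
    "her1_membrane": (5, 6, 7),
    "her1_cytoplasm": (5, 6, 7),
    "her3_membrane": (80,),
    "her3_cytoplasm": (80,),
    "her4_membrane": (8, 9),
    "her4_cytoplasm": (8, 9),
    "her2_membrane": (),
}

#: positives among the three stage-missing records (rows 198-200), fixed so
#: each marker's published total positive count is met exactly
_STAGE_MISSING_POSITIVES = {
    "her1_membrane": (198,),
    "her1_cytoplasm": (198,),
    "her2_membrane": (),
    "her3_membrane": (),
    "her3_cytoplasm": (198, 199),
    "her4_membrane": (198, 199),
    "her4_cytoplasm": (),
}


def study_replica_cohort(seed: int = 0) -> Cohort:
    """A 201-record cohort reproducing the published summary tables.

    Deterministic constraints (identical for every seed): categorical
    marginals, per-marker denominators, positives per stage group (hence
    marker totals), the 12 postoperative-death flags, ordinal 2+/3+ splits.
    Seed-dependent: which rows within a stage group carry the positive
    calls (biased toward membrane-HER2-positive rows to approximate the
    published pairwise agreement), the covariate-to-row pairing (biased so
    HER2/HER3 positivity is enriched in intestinal-type and older patients,
    as observed), and the survival draw from the calibrated cure model.
    """
    rng = np.random.default_rng(seed)
    n = ref.N_TOTAL
    df = pd.DataFrame({"id": [f"P{i + 1:04d}" for i in range(n)]})

    # --- stage: contiguous blocks 0/I/II | III/IV M0 | IV M1 | missing
    stage = []
    for lv, count in ref.COHORT_MARGINALS["stage"]:
        stage += [lv] * count
    stage += [pd.NA] * (n - len(stage))
    df["stage"] = pd.array(stage, dtype="string")

    # --- ordinal marker scores meeting the published counts exactly
    group_rows = {0: np.arange(75), 1: np.arange(75, 168), 2: np.arange(168, 198)}
    pos_by_marker: dict[str, np.ndarray] = {}
    calls = {}
    her2_rows = None
    ordered = ["her2_membrane"] + [m for m in MARKER_COLUMNS if m != "her2_membrane"]
    pub = {p.marker: p for p in ref.POSITIVITY_BY_STAGE}
    for m in ordered:
        missing_rows = np.array(_MISSING_ROWS[m], dtype=int)
        call = np.zeros(n)
        call[missing_rows] = np.nan
        chosen: list[int] = []
        for g in range(3):
            rows = np.setdiff1d(group_rows[g], missing_rows)
            n_pos = pub[m].positives[g] if m in pub else (1 if (m == "her3_membrane" and g == 1) else 0)
            if m == ANCHOR_MARKER or her2_rows is None:
                pick = rng.choice(rows, size=n_pos, replace=False)
            else:
                pick = _biased_pick(rng, rows, n_pos, her2_rows, _conditional_rate(m))
            chosen += list(pick)
        chosen += list(_STAGE_MISSING_POSITIVES[m])
        call[np.array(chosen, dtype=int)] = 1.0
        calls[m] = call
        pos_by_marker[m] = np.array(chosen, dtype=int)
        if m == ANCHOR_MARKER:
            her2_rows = set(chosen)
        n2, n3 = ref.ORDINAL_SPLITS[m]
        df[m] = _ordinal_from_calls(call, n2, n3, rng)

    # --- covariates: exact marginals, pairing biased where associations
    #     were published (HER2/HER3-cytoplasm positives lean intestinal, older)
    her2 = np.nan_to_num(calls["her2_membrane"])
    her3c = np.nan_to_num(calls["her3_cytoplasm"])
    pref = her2 * 2.0 + her3c * 1.0
    df["lauren"] = _allocate_with_preference(
        rng, n, ref.COHORT_MARGINALS["lauren"], prefer_level="intestinal", weight=np.exp(pref))
    for fld in ("sex", "location", "radicality", "lymphadenectomy", "pt", "pn", "adjuvant"):
        df[fld] = _allocate_with_preference(rng, n, ref.COHORT_MARGINALS[fld])

    ages = np.round(np.concatenate([
        np.linspace(ref.AGE_RANGE[0], 61, 100), [ref.AGE_MEDIAN],
        np.linspace(63, ref.AGE_RANGE[1], 100),
    ]))
    score = pref + rng.normal(0, 1.6, size=n)
    df["age"] = ages[np.argsort(np.argsort(score))]

    # --- survival: 12 postoperative deaths + calibrated cure model for 189
    postop = rng.choice(n, size=ref.N_POSTOP_DEATHS, replace=False)
    is_postop = np.zeros(n, dtype=bool)
    is_postop[postop] = True
    cfg = SyntheticConfig(n=n)
    times, events = simulate_survival(cfg, seed=int(rng.integers(2**31 - 1)))
    times[is_postop] = np.round(rng.uniform(0.1, 1.5, size=ref.N_POSTOP_DEATHS), 2)
    events[is_postop] = 1
    df["time_months"] = np.round(times, 3)
    df["event"] = pd.array(events, dtype="Int64")
    df["postop_death"] = pd.array(is_postop.astype(int), dtype="Int64")

    for col in ALL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.array([pd.NA] * n, dtype="string")
    return Cohort(df[list(ALL_COLUMNS)].copy(), provenance=f"study_replica_cohort(seed={seed})")


def _conditional_rate(marker: str) -> float:
    """Published P(marker positive | membrane HER2 positive) from the pair table."""
    for p in ref.PAIRWISE_TABLES:
        a, b, c, d = p.cells
        if p.marker_a == ANCHOR_MARKER and p.marker_b == marker:
            return a / (a + b) if a + b else 0.0
        if p.marker_b == ANCHOR_MARKER and p.marker_a == marker:
            return a / (a + c) if a + c else 0.0
    return float("nan")


def _biased_pick(rng, rows, n_pos, her2_rows, cond_rate) -> np.ndarray:
    """Pick n_pos rows, aiming the published share of them at HER2+ rows."""
    rows = np.asarray(rows)
    if np.isnan(cond_rate):
        return rng.choice(rows, size=n_pos, replace=False)
    in_pos = np.array([r in her2_rows for r in rows])
    pos_rows, neg_rows = rows[in_pos], rows[~in_pos]
    want_pos = int(round(cond_rate * len(pos_rows)))
    want_pos = max(0, min(want_pos, n_pos, len(pos_rows)))
    want_pos = max(want_pos, n_pos - len(neg_rows))
    picked = list(rng.choice(pos_rows, size=want_pos, replace=False)) if want_pos else []
    picked += list(rng.choice(neg_rows, size=n_pos - want_pos, replace=False))
    return np.array(picked, dtype=int)


def _ordinal_from_calls(call: np.ndarray, n2: int, n3: int, rng) -> np.ndarray:
    score = np.full(len(call), np.nan)
    pos = np.where(call == 1)[0]
    neg = np.where(call == 0)[0]
    n3_here = min(n3, len(pos))
    three = rng.choice(pos, size=n3_here, replace=False) if n3_here else np.array([], dtype=int)
    score[pos] = 2.0
    score[three] = 3.0
    ones = rng.choice(neg, size=len(neg) // 2, replace=False) if len(neg) else np.array([], dtype=int)
    score[neg] = 0.0
    score[ones] = 1.0
    return score


def _allocate_with_preference(rng, n, level_counts, prefer_level=None, weight=None):
    """Assign categorical levels with exact counts; remainder missing.

    With a preference, rows with high weight are likelier to receive
    ``prefer_level``; other levels fill the rest uniformly at random.
    """
    values = np.array([None] * n, dtype=object)
    rows = np.arange(n)
    if prefer_level is not None:
        counts = dict(level_counts)
        k = counts[prefer_level]
        w = np.asarray(weight, dtype=float)
        w = w / w.sum()
        chosen = rng.choice(rows, size=k, replace=False, p=w)
        values[chosen] = prefer_level
        rows = np.setdiff1d(rows, chosen)
        level_counts = [(lv, c) for lv, c in level_counts if lv != prefer_level]
    rows = rng.permutation(rows)
    i = 0
    for lv, c in level_counts:
        values[rows[i:i + c]] = lv
        i += c
    return pd.array([v if v is not None else pd.NA for v in values], dtype="string")
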