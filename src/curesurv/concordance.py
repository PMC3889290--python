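"""Marker agreement and association battery.

Cross-tabulations of dichotomized IHC calls, Cohen's kappa, the McNemar
test of marginal homogeneity (uncorrected, as in the source analysis),
Pearson's chi-square for marker-by-covariate association, and the
positivity-by-stage summary.

Conventions fixed by the analysis being reproduced: McNemar without
continuity correction, chi-square without Yates correction and without
exact tests, kappa unweighted on binary calls, p-values displayed to three
decimals with ``<0.001`` below 0.0005.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


from .cohort import Cohort, marker_calls, stage_groups, STAGE_GROUPS

logger = logging.getLogger("curesurv")


@dataclass
class ContingencyTable:
    """r x c table of nonnegative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or (self.counts < 0).any():
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(int)
        if len(self.row_labels) != self.counts.shape[0] or len(self.col_labels) != self.counts.shape[1]:
            raise ValueError("label lengths do not match table shape")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.col_labels, self.row_labels)


@dataclass
class AgreementResult:
    kappa: float
    mcnemar_stat: float
    mcnemar_p: float
    n: int
    table: ContingencyTable = field(repr=False, default=None)
    degenerate: bool = False


def table2x2(a: int, b: int, c: int, d: int) -> ContingencyTable:
    """2x2 table in (pos,pos),(pos,neg),(neg,pos),(neg,neg) cell order."""
    return ContingencyTable(np.array([[a, b], [c, d]]), ("pos", "neg"), ("pos", "neg"))


def crosstab(calls_a, calls_b, labels=("pos", "neg")) -> ContingencyTable:
    """2x2 cross-tabulation of two aligned binary call vectors.

    Pairs with either value missing are dropped (pairwise complete cases);
    cell [0,0] counts (pos, pos), cell [1,1] (neg, neg).
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) == 0:
        logger.warning("crosstab: no complete pairs; degenerate empty table")
    counts = np.array(
        [
            [int(((a == 1) & (b == 1)).sum()), int(((a == 1) & (b == 0)).sum())],
            [int(((a == 0) & (b == 1)).sum()), int(((a == 0) & (b == 0)).sum())],
        ]
    )
    return ContingencyTable(counts, labels, labels)


def cohen_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e) on a 2x2 table."""
    t = table.counts.astype(float)
    if t.shape != (2, 2):
        raise ValueError("cohen_kappa expects a 2x2 table")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    p_o = np.trace(t) / n
    row = t.sum(axis=1) / n
    col = t.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise ZeroDivisionError(
            "kappa undefined: both raters constant (expected agreement is 1)"
        )
    return float((p_o - p_e) / (1.0 - p_e))


def mcnemar_test(table: ContingencyTable) -> tuple[float, float]:
    """Uncorrected McNemar test on the discordant cells of a 2x2 table.

    stat = (b - c)^2 / (b + c), p from the chi-square(1) upper tail.
    Depends only on the off-diagonal cells.  b = c = 0 is degenerate:
    returns (0, 1) with a logged warning.
    """
    t = table.counts
    if t.shape != (2, 2):
        raise ValueError("mcnemar_test expects a 2x2 table")
    b, c = int(t[0, 1]), int(t[1, 0])
    if b + c == 0:
        logger.warning("mcnemar: no discordant pairs; degenerate (stat 0, p 1)")
        return 0.0, 1.0
    stat = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def pearson_chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Expected counts from the marginal products; df = (r-1)(c-1); small
    expected counts (< 5) are logged, not fatal.  A zero row or column
    marginal is a hard error naming the empty level.
    """
    t = table.counts.astype(float)
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    for margin, labels, which in ((rows, table.row_labels, "row"), (cols, table.col_labels, "column")):
        if (margin == 0).any():
            lab = labels[int(np.argmax(margin == 0))]
            raise ValueError(f"zero {which} marginal for level {lab!r}")
    expected = np.outer(rows, cols) / n
    if (expected < 5).any():
        logger.warning("chi-square: %d expected cell(s) below 5", int((expected < 5).sum()))
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df=df))
    return stat, df, p


def pair_agreement(cohort: Cohort, marker_a: str, marker_b: str) -> AgreementResult:
    """Kappa + McNemar for one marker pair on pairwise complete cases."""
    table = crosstab(marker_calls(cohort, marker_a), marker_calls(cohort, marker_b))
    return agreement_from_table(table)


def agreement_from_table(table: ContingencyTable) -> AgreementResult:
    b, c = int(table.counts[0, 1]), int(table.counts[1, 0])
    degenerate = b + c == 0
    stat, p = mcnemar_test(table)
    return AgreementResult(
        kappa=cohen_kappa(table), mcnemar_stat=stat, mcnemar_p=p, n=table.n,
        table=table, degenerate=degenerate,
    )


def positivity_by_stage(cohort: Cohort, marker: str) -> pd.DataFrame:
    """Positives/denominator and percent positive per TNM stage group.

    Denominators count non-missing marker calls within each group; the
    percentage is rounded to the nearest integer as in the published
    display.  A group with denominator 0 has an undefined (NaN) rate.
    """
    calls = marker_calls(cohort, marker)
    groups = stage_groups(cohort)
    rows = []
    for g in STAGE_GROUPS:
        sel = (groups == g).fillna(False).to_numpy()
        vals = calls[sel].dropna()
        denom = int(len(vals))
        pos = int(vals.sum())
        rate = round(100.0 * pos / denom) if denom else np.nan
        if denom == 0:
            logger.warning("positivity_by_stage: marker %s has empty denominator in %s", marker, g)
        rows.append({"stage_group": g, "positives": pos, "denominator": denom, "percent": rate})
    return pd.DataFrame(rows)


def stage_association_table(cohort: Cohort, marker: str) -> ContingencyTable:
    """2 x 3 (call x stage-group) table for the chi-square stage association."""
    pos = positivity_by_stage(cohort, marker)
    counts = np.array(
        [pos["positives"].to_numpy(), (pos["denominator"] - pos["positives"]).to_numpy()]
    )
    return ContingencyTable(counts.astype(int), ("pos", "neg"), tuple(pos["stage_group"]))


def association_battery(
    cohort: Cohort, marker: str, covariates: list[str], age_cut: float | None = None
) -> list[dict]:
    """Chi-square association between one marker and each categorical covariate.

    ``age`` is dichotomized at ``age_cut`` (default: cohort median).  Each
    entry reports the statistic, df, p (with display formatting), and the
    underlying cross-tabulation.
    """
    calls = marker_calls(cohort, marker)
    out = []
    for cov in covariates:
        if cov == "age":
            cut = age_cut if age_cut is not None else float(cohort.df["age"].median())
            values = pd.Series(
                np.where(cohort.df["age"].isna(), None,
                         np.where(cohort.df["age"] > cut, f">{cut:g}", f"<={cut:g}")),
                index=cohort.df.index,
            )
        elif cov == "stage_group":
            values = stage_groups(cohort)
        else:
            values = cohort.df[cov]
        keep = (~calls.isna()) & (~values.isna())
        levels = sorted(pd.unique(values[keep].dropna()))
        if len(levels) < 2:
            raise ValueError(f"covariate {cov!r} has a single level among complete cases")
        counts = np.array(
            [
                [int(((calls == s) & (values == lv) & keep).sum()) for lv in levels]
                for s in (1.0, 0.0)
            ]
        )
        table = ContingencyTable(counts, ("pos", "neg"), tuple(levels))
        stat, df, p = pearson_chi_square(table)
        out.append(
            {
                "marker": marker,
                "covariate": cov,
                "stat": stat,
                "df": df,
                "p": p,
                "p_display": format_p(p),
                "table": table,
            }
        )
    return out


def format_p(p: float, decimals: int = 3) -> str:
    """Publication-style p: three decimals, '<0.001' below 0.0005."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.{decimals}f}"
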