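"""Patient-cohort container, I/O, scoring and exclusion rules.

A cohort is a flat table, one row per patient, holding survival outcome
(months since surgery, death indicator, postoperative-death flag), clinical
covariates, and HER-family immunohistochemistry (IHC) scores on the ordinal
0/1+/2+/3+ staining scale, one column per receptor/compartment pair
(e.g. ``her2_membrane``).  Missing values are empty cells or ``NA``.

The module applies the study's analysis rules:

* IHC dichotomization — scores 0/1+ are negative, 2+/3+ positive;
* exclusion of postoperative deaths before any survival analysis;
* TNM stage grouping into 0/I/II, III/IV M0, and IV M1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("curesurv")

# ---------------------------------------------------------------- vocabulary

RECEPTORS = ("her1", "her2", "her3", "her4")

#: receptor/compartment pairs that carry an IHC score column.
#: HER2 is scored on the membrane only (per gastric-cancer consensus rules).
MARKER_COLUMNS = (
    "her1_membrane",
    "her1_cytoplasm",
    "her2_membrane",
    "her3_membrane",
    "her3_cytoplasm",
    "her4_membrane",
    "her4_cytoplasm",
)

#: the six markers with enough positives to enter pairwise agreement analyses
#: (membrane HER3 is near-absent: a single positive in the study population).
INFORMATIVE_MARKERS = (
    "her1_membrane",
    "her1_cytoplasm",
    "her2_membrane",
    "her3_cytoplasm",
    "her4_membrane",
    "her4_cytoplasm",
)

SEX_LEVELS = ("male", "female")
LAUREN_LEVELS = ("intestinal", "diffuse", "mixed")
LOCATION_LEVELS = ("stomach", "egj")
RADICALITY_LEVELS = ("R0", "R1", "R2")
LYMPHADENECTOMY_LEVELS = ("D0", "D1", "D2", "NR")
PT_LEVELS = ("Tis", "T1", "T2", "T3", "T4")
PN_LEVELS = ("N0", "N1", "N2", "N3")
STAGE_LEVELS = ("0", "IA", "IB", "II", "IIIA", "IIIB", "IVM0", "IVM1")
ADJUVANT_LEVELS = ("surgery_alone", "chemoradiotherapy")

STAGE_GROUPS = ("0_I_II", "III_IV_M0", "IV_M1")

_STAGE_TO_GROUP = {
    "0": "0_I_II",
    "IA": "0_I_II",
    "IB": "0_I_II",
    "II": "0_I_II",
    "IIIA": "III_IV_M0",
    "IIIB": "III_IV_M0",
    "IVM0": "III_IV_M0",
    "IVM1": "IV_M1",
}

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "lauren": LAUREN_LEVELS,
    "location": LOCATION_LEVELS,
    "radicality": RADICALITY_LEVELS,
    "lymphadenectomy": LYMPHADENECTOMY_LEVELS,
    "pt": PT_LEVELS,
    "pn": PN_LEVELS,
    "stage": STAGE_LEVELS,
    "adjuvant": ADJUVANT_LEVELS,
}

MANDATORY_COLUMNS = ("id", "time_months", "event")

ALL_COLUMNS = (
    "id",
    "age",
    "sex",
    "lauren",
    "location",
    "radicality",
    "lymphadenectomy",
    "pt",
    "pn",
    "stage",
    "adjuvant",
    "time_months",
    "event",
    "postop_death",
    *MARKER_COLUMNS,
)

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "nr."}


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame."""

    df: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate patient id {dup!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), self.provenance)


# ------------------------------------------------------------------ reading


def default_schema() -> dict:
    """Column-mapping contract used by :func:`read_cohort`.

    ``columns`` maps file headers to canonical names (identity by default);
    ``levels`` maps, per categorical field, lower-cased file spellings to
    canonical levels.  Matching is case-insensitive.
    """
    levels = {fld: {lv.lower(): lv for lv in lvs} for fld, lvs in _CATEGORICAL_LEVELS.items()}
    # common alternative spellings
    levels["sex"].update({"m": "male", "f": "female"})
    levels["location"].update({"esophagogastric junction": "egj"})
    levels["lauren"].update(
        {"intestinal type": "intestinal", "diffuse type": "diffuse", "mixed type": "mixed"}
    )
    levels["stage"].update({"iv m0": "IVM0", "iv m1": "IVM1"})
    levels["adjuvant"].update({"surgery": "surgery_alone"})
    return {"columns": {}, "levels": levels}


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


def read_cohort(path, schema_config: dict | None = None, sep: str | None = None) -> Cohort:
    """Read a delimited cohort table (comma default, tab accepted).

    Unparseable categorical levels become missing with a logged warning;
    a missing mandatory column or a negative survival time is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema_config or default_schema()
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = {c: schema.get("columns", {}).get(c, c) for c in raw.columns}
    raw = raw.rename(columns=colmap)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path.name}")

    out = pd.DataFrame(index=raw.index)
    out["id"] = raw["id"].astype(str)

    times = pd.to_numeric(raw["time_months"], errors="coerce")
    bad = times < 0
    if bad.any():
        rid = out.loc[bad, "id"].iloc[0]
        raise ValueError(f"negative survival time for record id {rid!r}")
    out["time_months"] = times

    out["event"] = pd.to_numeric(raw["event"], errors="coerce").astype("Int64")
    if "postop_death" in raw.columns:
        out["postop_death"] = pd.to_numeric(raw["postop_death"], errors="coerce").astype("Int64")
    else:
        out["postop_death"] = pd.array([0] * len(raw), dtype="Int64")

    if "age" in raw.columns:
        out["age"] = pd.to_numeric(raw["age"], errors="coerce")
    else:
        out["age"] = np.nan

    level_maps = schema.get("levels", {})
    for fld in _CATEGORICAL_LEVELS:
        if fld not in raw.columns:
            out[fld] = pd.Series([pd.NA] * len(raw), dtype="string")
            continue
        mapping = level_maps.get(fld, {})
        parsed = []
        for v in raw[fld]:
            if _is_missing(v):
                parsed.append(pd.NA)
                continue
            key = str(v).strip().lower()
            if key in mapping:
                parsed.append(mapping[key])
            else:
                logger.warning("unparseable %s level %r recorded as missing", fld, v)
                parsed.append(pd.NA)
        out[fld] = pd.Series(parsed, dtype="string")

    for col in MARKER_COLUMNS:
        if col not in raw.columns:
            out[col] = np.nan
            continue
        vals = []
        for i, v in enumerate(raw[col]):
            if _is_missing(v):
                vals.append(np.nan)
                continue
            s = float(str(v).strip().rstrip("+"))
            if s not in (0.0, 1.0, 2.0, 3.0):
                raise ValueError(
                    f"IHC score {v!r} outside 0..3 in column {col} (record id {out['id'].iloc[i]!r})"
                )
            vals.append(s)
        out[col] = vals

    cohort = Cohort(out[list(ALL_COLUMNS)], provenance=str(path))
    _check_invariants(cohort)
    return cohort


def _check_invariants(cohort: Cohort) -> None:
    df = cohort.df
    bad = (df["postop_death"].fillna(0).astype(int) == 1) & (df["event"].fillna(0).astype(int) != 1)
    if bad.any():
        rid = df.loc[bad, "id"].iloc[0]
        raise ValueError(f"postop_death=1 requires event=1 (record id {rid!r})")


def write_cohort(cohort: Cohort, path, sep: str = ",") -> Path:
    """Write the normalized cohort table; round-trips all non-missing fields."""
    path = Path(path)
    df = cohort.df.copy()
    for col in MARKER_COLUMNS:
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=sep, index=False, na_rep="")
    return path


def validation_report(cohort: Cohort) -> dict:
    """JSON-able per-column summary: dtype, missing count, level counts."""
    df = cohort.df
    report: dict = {"n_records": len(df), "provenance": cohort.provenance, "columns": {}}
    for col in df.columns:
        entry: dict = {"missing": int(df[col].isna().sum())}
        if col in _CATEGORICAL_LEVELS:
            entry["levels"] = {k: int(v) for k, v in df[col].value_counts().items()}
        report["columns"][col] = entry
    return report


# -------------------------------------------------------------- study rules


def dichotomize_ihc(score) -> float:
    """Binary marker call from an ordinal IHC score.

    0/1+ are negative (0.0), 2+/3+ positive (1.0), missing stays missing (nan).
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return np.nan
    if score not in (0, 1, 2, 3):
        raise ValueError(f"IHC score {score!r} outside 0..3")
    return 1.0 if score >= 2 else 0.0


def marker_calls(cohort: Cohort, marker: str) -> pd.Series:
    """Dichotomized calls for one receptor/compartment column (nan = missing)."""
    if marker not in MARKER_COLUMNS:
        raise KeyError(f"unknown marker {marker!r}")
    return cohort.df[marker].map(dichotomize_ihc)


def exclude_postoperative_deaths(cohort: Cohort) -> Cohort:
    """Drop patients who died in the postoperative period (idempotent)."""
    keep = cohort.df["postop_death"].fillna(0).astype(int) == 0
    out = cohort.df.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("all records flagged as postoperative deaths; empty cohort returned")
    return Cohort(out, provenance=cohort.provenance + " [postop deaths excluded]")


def assign_stage_group(stage) -> str:
    """Collapse TNM stage into the three analysis groups.

    0/IA/IB/II -> ``0_I_II``; IIIA/IIIB/IVM0 -> ``III_IV_M0``; IVM1 -> ``IV_M1``.
    Missing propagates; an unknown stage label is a hard error.
    """
    if pd.isna(stage):
        return pd.NA
    stage = str(stage)
    if stage not in _STAGE_TO_GROUP:
        raise ValueError(f"unknown TNM stage {stage!r}")
    return _STAGE_TO_GROUP[stage]


def stage_groups(cohort: Cohort) -> pd.Series:
    return cohort.df["stage"].map(assign_stage_group).astype("string")


def data_dictionary() -> dict:
    """Machine-readable description of every cohort column."""
    dd = {
        "id": "opaque unique patient identifier",
        "age": "age at surgery, years",
        "sex": f"one of {SEX_LEVELS}",
        "lauren": f"Lauren histological classification, one of {LAUREN_LEVELS}",
        "location": f"tumor location, one of {LOCATION_LEVELS} (egj = esophagogastric junction)",
        "radicality": f"surgical resection radicality, one of {RADICALITY_LEVELS}",
        "lymphadenectomy": f"lymphadenectomy extent, one of {LYMPHADENECTOMY_LEVELS} (NR = not related)",
        "pt": f"pathological tumor depth, one of {PT_LEVELS}",
        "pn": f"pathological nodal status, one of {PN_LEVELS}",
        "stage": f"AJCC TNM stage group, one of {STAGE_LEVELS}",
        "adjuvant": f"adjuvant therapy, one of {ADJUVANT_LEVELS}",
        "time_months": "overall survival, months from surgery to death or censoring",
        "event": "1 = death from any cause, 0 = censored",
        "postop_death": "1 = died during the postoperative period (excluded from survival analysis)",
    }
    for col in MARKER_COLUMNS:
        dd[col] = "IHC staining score 0..3 (0/1+ negative, 2+/3+ positive); empty or NA = missing"
    return dd


def write_data_dictionary(path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(data_dictionary(), indent=2) + "\n")
    return path
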