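"""Published summary tables of the gastric-cancer cohort the package emulates.

The source study reports a 201-patient gastric / esophagogastric-junction
adenocarcinoma cohort (stages 0–IV, primary tumor resection) with HER-family
IHC scores.  Patient-level data were never deposited, so these printed
summaries are the only numeric anchors available:

* ``COHORT_MARGINALS`` — demographic / clinicopathological counts
  (totals per category; some categories do not sum to 201, the remainder
  is recorded missing rather than reconciled);
* ``PAIRWISE_TABLES`` — 2x2 cross-tabulations of dichotomized marker calls
  between the six informative receptor/compartment markers, with the
  published kappa coefficient and McNemar p-value for each pair;
* ``POSITIVITY_BY_STAGE`` — positives/denominator per TNM stage group
  with the published chi-square p-value;
* survival summary constants (analyzed n, deaths, censored, follow-up,
  cure fraction and its CI).

Two published kappas and two published stage-association p-values do not
recompute from their own printed counts (flagged ``verifiable=False``); they
are carried for completeness but never used as numeric oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ------------------------------------------------------- cohort composition

N_TOTAL = 201
N_POSTOP_DEATHS = 12
N_ANALYZED = 189          # after postoperative-death exclusion
N_DEATHS = 83             # among the 189 analyzed
N_CENSORED = 106
MEDIAN_FOLLOWUP_MONTHS = 30.26
CURE_FRACTION = 0.51
CURE_FRACTION_CI = (0.42, 0.59)

#: category -> list of (level, count); counts below 201 leave the rest missing
COHORT_MARGINALS: dict[str, list[tuple[str, int]]] = {
    "sex": [("male", 124), ("female", 77)],
    "location": [("stomach", 160), ("egj", 38)],
    "lauren": [("intestinal", 124), ("diffuse", 57), ("mixed", 16)],
    "radicality": [("R0", 150), ("R1", 16), ("R2", 33)],
    "lymphadenectomy": [("D0", 5), ("D1", 31), ("D2", 126), ("NR", 39)],
    "pt": [("Tis", 3), ("T1", 18), ("T2", 32), ("T3", 130), ("T4", 18)],
    "pn": [("N0", 69), ("N1", 66), ("N2", 41), ("N3", 21)],
    "stage": [
        ("0", 3), ("IA", 15), ("IB", 19), ("II", 38),
        ("IIIA", 49), ("IIIB", 25), ("IVM0", 19), ("IVM1", 30),
    ],
    "adjuvant": [("surgery_alone", 76), ("chemoradiotherapy", 125)],
}

AGE_MEDIAN = 62
AGE_RANGE = (27, 88)

#: per-marker number of evaluable samples (the rest are missing scores)
MARKER_DENOMINATORS = {
    "her1_membrane": 198,
    "her1_cytoplasm": 198,
    "her2_membrane": 201,
    "her3_membrane": 200,
    "her3_cytoplasm": 200,
    "her4_membrane": 199,
    "her4_cytoplasm": 199,
}

#: total positive calls per marker (2+/3+)
MARKER_POSITIVES = {
    "her1_membrane": 17,
    "her1_cytoplasm": 90,
    "her2_membrane": 34,
    "her3_membrane": 1,
    "her3_cytoplasm": 124,
    "her4_membrane": 29,
    "her4_cytoplasm": 49,
}

#: how positives split into 2+ : 3+ (published where stated, else even-ish)
ORDINAL_SPLITS = {
    "her1_membrane": (8, 9),       # 4 % scored 2+, 5 % scored 3+
    "her1_cytoplasm": (45, 45),
    "her2_membrane": (22, 12),     # 11 % scored 2+, 6 % scored 3+
    "her3_membrane": (1, 0),
    "her3_cytoplasm": (62, 62),
    "her4_membrane": (20, 9),      # 10 % scored 2+, 5 % scored 3+
    "her4_cytoplasm": (25, 24),
}


# --------------------------------------------------- pairwise marker tables


@dataclass(frozen=True)
class PublishedPair:
    """One published 2x2 agreement table between two binary marker calls.

    Cells are (a, b, c, d) = (pos/pos, pos/neg, neg/pos, neg/neg) with the
    first marker on rows.  ``kappa`` and ``mcnemar_p`` are the published
    values; ``p_lt_001`` marks pairs printed as "<0.001".  ``verifiable`` is
    False where the published kappa does not recompute from the cells.
    """

    marker_a: str
    marker_b: str
    cells: tuple[int, int, int, int]
    kappa: float
    mcnemar_p: float | None
    p_lt_001: bool = False
    verifiable: bool = True

    @property
    def counts(self) -> np.ndarray:
        a, b, c, d = self.cells
        return np.array([[a, b], [c, d]], dtype=int)


PAIRWISE_TABLES: tuple[PublishedPair, ...] = (
    PublishedPair("her1_membrane", "her1_cytoplasm", (13, 4, 77, 104), 0.115, None, True),
    PublishedPair("her1_membrane", "her2_membrane", (5, 12, 29, 152), 0.092, 0.008),
    PublishedPair("her1_membrane", "her3_cytoplasm", (13, 4, 109, 71), 0.042, None, True),
    PublishedPair("her1_membrane", "her4_membrane", (4, 13, 25, 156), 0.279, 0.052,
                  verifiable=False),  # recomputes to ~0.074
    PublishedPair("her1_membrane", "her4_cytoplasm", (5, 12, 44, 137), 0.028, None, True),
    PublishedPair("her1_cytoplasm", "her2_membrane", (17, 73, 17, 91), 0.033, None, True),
    PublishedPair("her1_cytoplasm", "her3_cytoplasm", (58, 31, 64, 44), 0.057, None, True),
    PublishedPair("her1_cytoplasm", "her4_membrane", (10, 80, 19, 89), 0.0, None, True,
                  verifiable=False),  # recomputes to ~-0.069
    PublishedPair("her1_cytoplasm", "her4_cytoplasm", (27, 63, 22, 86), 0.100, None, True),
    PublishedPair("her2_membrane", "her3_cytoplasm", (23, 11, 101, 65), 0.033, None, True),
    PublishedPair("her2_membrane", "her4_membrane", (7, 27, 22, 143), 0.077, 0.475),
    PublishedPair("her2_membrane", "her4_cytoplasm", (14, 20, 35, 130), 0.170, 0.043),
    PublishedPair("her3_cytoplasm", "her4_membrane", (24, 99, 5, 70), 0.103, None, True),
    PublishedPair("her3_cytoplasm", "her4_cytoplasm", (35, 88, 14, 61), 0.082, None, True),
    PublishedPair("her4_membrane", "her4_cytoplasm", (13, 16, 36, 134), 0.184, 0.006),
)

#: the 11 pairs whose published kappa the pipeline is required to reproduce
#: to the 3 printed decimals (pair key -> published kappa)
VERIFIED_KAPPAS = {
    ("her1_membrane", "her1_cytoplasm"): 0.115,
    ("her1_membrane", "her2_membrane"): 0.092,
    ("her1_membrane", "her3_cytoplasm"): 0.042,
    ("her1_membrane", "her4_cytoplasm"): 0.028,
    ("her1_cytoplasm", "her2_membrane"): 0.033,
    ("her1_cytoplasm", "her3_cytoplasm"): 0.057,
    ("her1_cytoplasm", "her4_cytoplasm"): 0.100,
    ("her2_membrane", "her4_membrane"): 0.077,
    ("her2_membrane", "her4_cytoplasm"): 0.170,
    ("her3_cytoplasm", "her4_membrane"): 0.103,
    ("her4_membrane", "her4_cytoplasm"): 0.184,
}

#: published McNemar p-values given numerically (pair key -> p)
PUBLISHED_MCNEMAR_P = {
    ("her1_membrane", "her2_membrane"): 0.008,
    ("her1_membrane", "her4_membrane"): 0.052,
    ("her2_membrane", "her4_membrane"): 0.475,
    ("her2_membrane", "her4_cytoplasm"): 0.043,
    ("her4_membrane", "her4_cytoplasm"): 0.006,
}


# ------------------------------------------------- positivity by TNM stage


@dataclass(frozen=True)
class PublishedPositivity:
    """Positives/denominator per stage group, with the published chi-square p."""

    marker: str
    positives: tuple[int, int, int]      # 0/I/II, III/IV M0, IV M1
    denominators: tuple[int, int, int]
    p: float
    verifiable: bool = True


POSITIVITY_BY_STAGE: tuple[PublishedPositivity, ...] = (
    PublishedPositivity("her1_membrane", (6, 9, 1), (72, 93, 30), 0.545),
    PublishedPositivity("her1_cytoplasm", (31, 44, 14), (72, 93, 30), 0.258,
                        verifiable=False),  # recomputes to ~0.856
    PublishedPositivity("her2_membrane", (14, 15, 5), (75, 93, 30), 0.907),
    PublishedPositivity("her3_cytoplasm", (43, 56, 23), (75, 92, 30), 0.176),
    PublishedPositivity("her4_membrane", (12, 11, 4), (73, 93, 30), 0.692),
    PublishedPositivity("her4_cytoplasm", (20, 24, 5), (73, 93, 30), 0.321,
                        verifiable=False),  # recomputes to ~0.505
)
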