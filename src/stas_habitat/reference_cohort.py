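"""Published reference-cohort statistics used for validation and simulation.

These are the baseline categorical counts of the 217-patient training cohort
of a published dual-center study of solid lung adenocarcinomas ≤ 2 cm with
pathologically evaluated spread through air spaces (STAS).  They serve two
purposes here:

* the odds-ratio routines in :mod:`~stas_habitat.evaluation_stats` are
  validated by recomputing the study's univariable ORs and Wald CIs from these
  counts (see :func:`univariable_or_table`);
* the phantom generator draws its clinical covariates from the corresponding
  marginal frequencies, so synthetic clinical tables have realistic mixes.

Counts are stored per variable as ``{category: (n_stas_positive,
n_stas_negative)}``.  Two printed rows of the study's regression table are
arithmetically inconsistent with these counts (SCCA, whose row duplicates
CYFRA's, and spiculation); they are excluded from verification and flagged in
:data:`INCONSISTENT_PRINTED_ROWS`.
"""

from __future__ import annotations

import logging

log = logging.getLogger(__name__)

# cohort sizes: single-center pool split 7:3 into training/validation, plus an
# external test cohort from the second center
CENTER1_N = 310
TRAINING_N = 217
VALIDATION_N = 93
TEST_N = 91
TRAINING_STAS_POSITIVE = 82
TRAINING_PREVALENCE = TRAINING_STAS_POSITIVE / TRAINING_N  # 0.3779...

# training-cohort categorical counts: category -> (STAS+, STAS-)
TRAINING_CATEGORICAL: dict[str, dict[str, tuple[int, int]]] = {
    "Sex": {"Male": (39, 65), "Female": (43, 70)},
    "Smoking history": {"Yes": (22, 39), "No": (60, 96)},
    "CEA (ng/mL)": {">5.0": (15, 21), "≤5.0": (67, 114)},
    "SCCA (ng/mL)": {">1.5": (3, 1), "≤1.5": (79, 134)},
    "NSE (ng/mL)": {">17.0": (30, 43), "≤17.0": (52, 92)},
    "CYFRA (ng/mL)": {">3.3": (15, 29), "≤3.3": (67, 106)},
    "Lobulation": {"Present": (74, 121), "Absent": (8, 14)},
    "Spiculation": {"Present": (27, 42), "Absent": (55, 93)},
    "Bronchial cut-off": {"Present": (21, 14), "Absent": (61, 121)},
    "Air bronchogram": {"Present": (29, 58), "Absent": (53, 77)},
    "Vacuole": {"Present": (27, 39), "Absent": (55, 96)},
}

# printed univariable OR (95% CI) for the verifiable exposure categories
PRINTED_UNIVARIABLE_OR: dict[str, tuple[float, float, float]] = {
    "Sex": (0.98, 0.56, 1.69),
    "Smoking history": (0.90, 0.49, 1.67),
    "CEA (ng/mL)": (1.22, 0.59, 2.52),
    "NSE (ng/mL)": (1.23, 0.69, 2.20),
    "CYFRA (ng/mL)": (0.82, 0.41, 1.64),
    "Lobulation": (1.07, 0.43, 2.67),
    "Bronchial cut-off": (2.98, 1.42, 6.25),
    "Vacuole": (1.21, 0.67, 2.18),
}

# exposure category (the non-reference level) per variable
EXPOSURE_CATEGORY = {
    "Sex": "Male",
    "Smoking history": "Yes",
    "CEA (ng/mL)": ">5.0",
    "SCCA (ng/mL)": ">1.5",
    "NSE (ng/mL)": ">17.0",
    "CYFRA (ng/mL)": ">3.3",
    "Lobulation": "Present",
    "Spiculation": "Present",
    "Bronchial cut-off": "Present",
    "Air bronchogram": "Present",
    "Vacuole": "Present",
}

#: printed regression rows that cannot be reproduced from the printed counts
INCONSISTENT_PRINTED_ROWS = {
    "SCCA (ng/mL)": "printed row duplicates CYFRA's although the counts differ",
    "Spiculation": "counts give OR 1.23 (0.68–2.21) but the row prints 1.09 (0.60–1.96)",
}


def contingency(variable: str) -> tuple[int, int, int, int]:
    """(a, b, c, d) = (exposed case, exposed control, unexposed case,
    unexposed control) for a training-cohort variable."""
    cats = TRAINING_CATEGORICAL[variable]
    exposed = EXPOSURE_CATEGORY[variable]
    (a, b) = cats[exposed]
    (c, d) = next(v for k, v in cats.items() if k != exposed)
    return a, b, c, d


def marginal_rate(variable: str) -> float:
    """Overall frequency of the exposure category in the training cohort."""
    a, b, c, d = contingency(variable)
    return (a + b) / (a + b + c + d)


def univariable_or_table() -> dict[str, dict[str, float]]:
    """Recompute univariable Wald ORs/CIs from the stored counts.

    Returns one row per verifiable variable; the two variables whose printed
    rows are inconsistent with their printed counts are skipped with a log
    message.
    """
    from .evaluation_stats import ContingencyTable2x2, odds_ratio_wald

    rows: dict[str, dict[str, float]] = {}
    for variable in PRINTED_UNIVARIABLE_OR:
        a, b, c, d = contingency(variable)
        res = odds_ratio_wald(ContingencyTable2x2(a, b, c, d))
        rows[variable] = {"or": res.odds_ratio, "ci_low": res.ci_low, "ci_high": res.ci_high}
    for variable, reason in INCONSISTENT_PRINTED_ROWS.items():
        log.info("excluded %s from OR verification: %s", variable, reason)
    return rows
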