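"""Longitudinal subject identification: filters, staging and panel building.

The flow mirrors the screening study's attrition pipeline: drop subjects by
examination count, drop dialysis-range subjects (any eGFR < 15), assign each
survivor to the experimental (stage 3a), control (stage 3b) or "others"
group from its eGFR trajectory, and emit a one-row-per-subject longitudinal
panel with the two predictor exams and the staging outcome.

Staging uses the subject's *last three* examinations: the two earlier exams
of the window must both be in the normal range (eGFR >= ``normal_floor``),
and the final exam's eGFR band decides the group.  Subjects matching neither
band (or without a normal-range run) fall into "others" and never reach the
panel.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import StageThresholds
from .variables import VARIABLE_CODES

logger = logging.getLogger(__name__)

GROUPS = ("experimental", "control", "others")


def filter_by_exam_count(
    records: pd.DataFrame, min_exams: int = 3, max_exams: int = 12
) -> pd.DataFrame:
    """Keep subjects whose examination count lies in ``[min_exams, max_exams]``."""
    if records.empty:
        logger.warning("filter_by_exam_count received an empty record table")
        return records.copy()
    counts = records.groupby("subject_id")["exam"].size()
    keep = counts[(counts >= min_exams) & (counts <= max_exams)].index
    out = records[records["subject_id"].isin(keep)].copy()
    n_removed = counts.size - len(keep)
    logger.info("exam-count filter removed %d of %d subjects", n_removed, counts.size)
    return out


def exclude_low_egfr(records: pd.DataFrame, threshold: float = 15.0) -> pd.DataFrame:
    """Drop every record of any subject with at least one eGFR below ``threshold``.

    The comparison is strict, so a minimum of exactly ``threshold`` is kept.
    """
    if records["egfr"].isna().any():
        bad = records.loc[records["egfr"].isna(), ["subject_id", "exam"]]
        raise ValueError(
            "eGFR missing on records: "
            + ", ".join(f"{r.subject_id}/exam{r.exam}" for r in bad.itertuples())
        )
    low = records.loc[records["egfr"] < threshold, "subject_id"].unique()
    out = records[~records["subject_id"].isin(low)].copy()
    logger.info(
        "eGFR exclusion removed %d subjects (%d records)",
        len(low),
        len(records) - len(out),
    )
    return out


def assign_group(subject_records: pd.DataFrame, thresholds: StageThresholds) -> str:
    """Label one subject's trajectory as experimental, control or others.

    The staging window is the last three exams.  Both pre-staging exams must
    be normal-range (>= ``normal_floor``); the staging exam's eGFR band then
    decides the label.  Bands are half-open ``[lo, hi)``.
    """
    ordered = subject_records.sort_values("exam")
    if len(ordered) < 3:
        raise ValueError(
            f"subject {ordered['subject_id'].iloc[0]!r} has fewer than 3 exams; "
            "exam-count filter contract violated"
        )
    window = ordered["egfr"].to_numpy()[-3:]
    if not (window[0] >= thresholds.normal_floor and window[1] >= thresholds.normal_floor):
        return "others"
    staging = window[2]
    e_lo, e_hi = thresholds.experimental_band
    c_lo, c_hi = thresholds.control_band
    if e_lo <= staging < e_hi:
        return "experimental"
    if c_lo <= staging < c_hi:
        return "control"
    return "others"


def build_panel(
    records: pd.DataFrame, thresholds: StageThresholds | None = None
) -> pd.DataFrame:
    """Build the longitudinal panel: one row per eligible subject.

    Columns are ``subject_id``, ``<code>_1`` and ``<code>_2`` for the two
    predictor exams of each of the 19 measurements, the ``group`` label, and
    the binary outcome ``Y`` (1 = experimental/progression, 0 = control).
    "Others" subjects are dropped.
    """
    thresholds = thresholds or StageThresholds()
    rows = []
    for sid, sub in records.sort_values(["subject_id", "exam"]).groupby("subject_id"):
        label = assign_group(sub, thresholds)
        if label == "others":
            continue
        window = sub.iloc[-3:]
        row: dict = {"subject_id": sid}
        for code in VARIABLE_CODES:
            row[f"{code}_1"] = window[code].iloc[0]
            row[f"{code}_2"] = window[code].iloc[1]
        row["group"] = label
        row["Y"] = 1 if label == "experimental" else 0
        rows.append(row)
    panel = pd.DataFrame(rows)
    if not panel.empty:
        panel["Y"] = panel["Y"].astype(int)
    logger.info(
        "panel built: %d subjects (%d progressors)",
        len(panel),
        int(panel["Y"].sum()) if not panel.empty else 0,
    )
    return panel


def build_cohort(
    records: pd.DataFrame,
    thresholds: StageThresholds | None = None,
    min_exams: int = 3,
    max_exams: int = 12,
) -> tuple[pd.DataFrame, dict]:
    """Run the full attrition pipeline and return (panel, attrition log).

    The attrition log counts subjects at every stage, mirroring the study's
    subject-identification flow chart.
    """
    thresholds = thresholds or StageThresholds()
    n0 = records["subject_id"].nunique()
    after_count = filter_by_exam_count(records, min_exams, max_exams)
    n1 = after_count["subject_id"].nunique()
    after_egfr = exclude_low_egfr(after_count, thresholds.egfr_exclusion)
    n2 = after_egfr["subject_id"].nunique()
    panel = build_panel(after_egfr, thresholds)
    attrition = {
        "subjects_input": int(n0),
        "removed_exam_count": int(n0 - n1),
        "removed_low_egfr": int(n1 - n2),
        "assigned_others": int(n2 - len(panel)),
        "experimental": int(panel["Y"].sum()) if not panel.empty else 0,
        "control": int((1 - panel["Y"]).sum()) if not panel.empty else 0,
        "panel_subjects": int(len(panel)),
    }
    return panel, attrition


def write_attrition(attrition: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(attrition, indent=2))
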