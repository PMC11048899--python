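"""Cohort filters, staging and panel construction."""

import numpy as np
import pandas as pd
import pytest

from verselect.cohort import (
    assign_group,
    build_cohort,
    build_panel,
    exclude_low_egfr,
    filter_by_exam_count,
)
from verselect.config import GeneratorConfig, StageThresholds
from verselect.synthetic import (
    RECORD_COLUMNS,
    generate_cohort,
    generate_degenerate_subjects,
)
from verselect.variables import VARIABLE_CODES


def _records(spec):
    """Build a record table from {subject: [egfr per exam]}."""
    rows = []
    for sid, egfrs in spec.items():
        for t, egfr in enumerate(egfrs, start=1):
            rows.append([sid, t, *[50.0] * len(VARIABLE_CODES), egfr])
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def test_exam_count_filter_boundaries():
    spec = {f"S{k}": [70.0] * k for k in range(1, 14)}
    out = filter_by_exam_count(_records(spec))
    counts = out.groupby("subject_id")["exam"].size()
    # counts 3..12 survive; 1, 2 and 13 are removed
    assert sorted(counts) == list(range(3, 13))


def test_exam_count_filter_enumerated_cohort():
    spec = {f"S{k}": [70.0] * k for k in range(1, 11)}
    out = filter_by_exam_count(_records(spec))
    assert out["subject_id"].nunique() == 8


def test_low_egfr_excludes_whole_subject():
    records = _records({"A": [70.0, 14.0, 80.0], "B": [70.0, 70.0, 40.0]})
    out = exclude_low_egfr(records)
    assert set(out["subject_id"]) == {"B"}
    assert len(out) == 3  # every record of A is gone


def test_low_egfr_threshold_is_strict():
    records = _records({"A": [70.0, 15.0, 40.0]})
    out = exclude_low_egfr(records)
    assert set(out["subject_id"]) == {"A"}


def test_low_egfr_missing_value_rejected():
    records = _records({"A": [70.0, np.nan, 40.0]})
    with pytest.raises(ValueError, match="A"):
        exclude_low_egfr(records)


def test_degenerate_fixture_filtered_as_designed():
    table = generate_degenerate_subjects()
    after_egfr = exclude_low_egfr(table)
    assert "D_dialysis" not in set(after_egfr["subject_id"])
    after_count = filter_by_exam_count(after_egfr)
    assert set(after_count["subject_id"]) == set()


def test_filters_commute():
    """Exam-count and eGFR filters are per-subject predicates, so their
    order does not matter."""
    table = pd.concat(
        [
            generate_degenerate_subjects(),
            generate_cohort(GeneratorConfig(n_subjects=20, seed=4)).records,
        ],
        ignore_index=True,
    )
    a = exclude_low_egfr(filter_by_exam_count(table))
    b = filter_by_exam_count(exclude_low_egfr(table))
    pd.testing.assert_frame_equal(
        a.sort_values(["subject_id", "exam"]).reset_index(drop=True),
        b.sort_values(["subject_id", "exam"]).reset_index(drop=True),
    )


def test_assign_group_bands():
    th = StageThresholds()
    assert assign_group(_records({"A": [95.0, 92.0, 91.0]}), th) == "others"
    assert assign_group(_records({"A": [70.0, 65.0, 50.0]}), th) == "experimental"
    assert assign_group(_records({"A": [70.0, 65.0, 40.0]}), th) == "control"
    # normal-floor requirement on the two predictor exams
    assert assign_group(_records({"A": [70.0, 55.0, 40.0]}), th) == "others"
    # band edges are half-open
    assert assign_group(_records({"A": [70.0, 65.0, 45.0]}), th) == "experimental"
    assert assign_group(_records({"A": [70.0, 65.0, 60.0]}), th) == "others"


def test_assign_group_requires_three_exams():
    with pytest.raises(ValueError, match="fewer than 3"):
        assign_group(_records({"A": [70.0, 65.0]}), StageThresholds())


def test_assign_group_recovers_planted_labels(planted_cohort):
    th = StageThresholds()
    truth = planted_cohort.truth.set_index("subject_id")["group"]
    for sid, sub in planted_cohort.records.groupby("subject_id"):
        assert assign_group(sub, th) == truth[sid]


def test_panel_uses_first_two_window_exams():
    records = _records({"A": [70.0, 65.0, 50.0]})
    for code in VARIABLE_CODES:
        records[code] = [10.0, 12.0, 99.0]  # staging-exam value must not leak
    panel = build_panel(records)
    assert len(panel) == 1
    row = panel.iloc[0]
    assert row["BUN_1"] == 10.0 and row["BUN_2"] == 12.0
    assert row["Y"] == 1


def test_panel_invariant_to_row_order():
    cohort = generate_cohort(GeneratorConfig(n_subjects=40, seed=6))
    shuffled = cohort.records.sample(frac=1.0, random_state=0)
    a = build_panel(cohort.records).reset_index(drop=True)
    b = build_panel(shuffled).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_build_cohort_accounting(default_cohort):
    panel, attrition = build_cohort(default_cohort.records)
    assert len(panel) == 335
    assert int(panel["Y"].sum()) == 33
    assert attrition["experimental"] + attrition["control"] == attrition["panel_subjects"]
    assert attrition["subjects_input"] == (
        attrition["removed_exam_count"]
        + attrition["removed_low_egfr"]
        + attrition["assigned_others"]
        + attrition["panel_subjects"]
    )
    assert set(panel["group"]) == {"experimental", "control"}
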