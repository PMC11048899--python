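"""Apply the subject-identification flow and build the longitudinal panel.

Filters the generated record table (exam count 3-12, any eGFR < 15
excludes the subject), assigns stage groups from the eGFR trajectory, and
writes the per-subject panel (two predictor exams + outcome) with an
attrition log.

Run after 01:  python analysis/02_build_panel.py
"""

from pathlib import Path

from verselect.cohort import build_cohort, write_attrition
from verselect.synthetic import read_records

OUT = Path("results")


def main() -> None:
    for name in ("cohort_default", "cohort_planted_n1000"):
        records = read_records(OUT / f"{name}.csv")
        panel, attrition = build_cohort(records)
        panel.to_csv(OUT / f"{name}.panel.csv", index=False)
        write_attrition(attrition, OUT / f"{name}.attrition.json")
        print(
            f"{name}: {attrition['panel_subjects']} eligible subjects "
            f"({attrition['experimental']} experimental / "
            f"{attrition['control']} control); "
            f"removed {attrition['removed_exam_count']} by exam count, "
            f"{attrition['removed_low_egfr']} by eGFR, "
            f"{attrition['assigned_others']} as others"
        )


if __name__ == "__main__":
    main()
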