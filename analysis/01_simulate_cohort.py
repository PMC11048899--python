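"""Generate the study cohorts.

Produces two synthetic longitudinal screening cohorts under results/:

* ``cohort_default`` — the study-sized cohort (335 subjects, 3 exams each,
  33 progressors) with the three default planted effects (BUN(S), Hb(S),
  RBC(M), standardised log-odds 2.0);
* ``cohort_planted_n1000`` — the same structure at n=1000, used for model
  fitting and selection downstream.

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from verselect.config import GeneratorConfig, save_config
from verselect.experiments import DEFAULT_PLANTED
from verselect.synthetic import generate_cohort, write_manifest, write_records

OUT = Path("results")


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    for name, n in (("cohort_default", 335), ("cohort_planted_n1000", 1000)):
        config = GeneratorConfig(
            n_subjects=n, class_ratio=33 / 335, effect_spec=DEFAULT_PLANTED, seed=seed
        )
        cohort = generate_cohort(config)
        write_records(cohort.records, OUT / f"{name}.csv")
        write_manifest(cohort.manifest, OUT / f"{name}.manifest.json")
        save_config(config, OUT / f"{name}.config.yaml")
        m = cohort.manifest
        print(
            f"{name}: {m['n_subjects']} subjects, {m['n_records']} records, "
            f"{m['n_positive']} progressors (seed={seed})"
        )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
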