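"""Refit the selector model on every selection condition.

Re-runs the cross-validation harness (same seed, hence the same outer
folds as the baseline) restricted to each of the ten union-selected
variable sets, and compares against the all-76-variable baseline — the
condition curve showing whether selection preserves or improves AUC.

Run after 05:  python analysis/06_evaluate_selections.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from verselect.config import CVConfig
from verselect.evaluate import sweep_conditions
from verselect.models import FAST_GRIDS, get_model_spec

OUT = Path("results")


def main(seed: int = 1) -> None:
    features = pd.read_csv(OUT / "cohort_planted_n1000.features.csv")
    aggregated = pd.read_csv(OUT / "aggregated.csv", index_col="variable")
    conditions, _ = sweep_conditions(
        features, aggregated, get_model_spec("lasso", FAST_GRIDS), CVConfig(seed=seed)
    )
    conditions.round(6).to_csv(OUT / "conditions.csv", index=False)
    print(conditions[["rule", "k", "n_selected", "AUC", "AUC_sd", "BA"]]
          .round(3).to_string(index=False))
    base = conditions.loc[conditions["rule"] == "all", "AUC"].iloc[0]
    best = conditions.loc[conditions["rule"] != "all"].nlargest(1, "AUC").iloc[0]
    print(
        f"baseline AUC {base:.3f} (76 variables); best condition "
        f"{best['rule']} k={int(best['k'])} -> AUC {best['AUC']:.3f} "
        f"with {int(best['n_selected'])} variables"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
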