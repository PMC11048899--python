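"""Fit the model zoo under nested cross-validation and extract importances.

Runs the six ensemble members and the logistic benchmark through 10-fold
nested CV (training folds oversampled to parity) on the n=1000 planted
cohort, then converts the fold-merged importances to RIV (min-max, 0-100)
and ORV (descending rank) profiles.

Run after 03:  python analysis/04_rank_importance.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from verselect.config import CVConfig
from verselect.cv import run_nested_cv, summarize_metrics
from verselect.features import feature_array
from verselect.importance import importance_tables
from verselect.models import BENCHMARK_MODEL, ENSEMBLE_MODELS, FAST_GRIDS, get_model_spec

OUT = Path("results")


def main(seed: int = 1) -> None:
    features = pd.read_csv(OUT / "cohort_planted_n1000.features.csv")
    X, y, cols = feature_array(features)
    cv = CVConfig(seed=seed)
    results = []
    for name in (*ENSEMBLE_MODELS, BENCHMARK_MODEL):
        res = run_nested_cv(X, y, cols, get_model_spec(name, FAST_GRIDS), cv)
        results.append(res)
        res.metrics.drop(columns=["params"]).to_csv(OUT / f"folds_{name}.csv")
    summary = pd.DataFrame({r.model: summarize_metrics(r.metrics) for r in results}).T
    summary.to_csv(OUT / "model_metrics.csv")
    print("fold-mean performance:")
    print(summary[["BA", "SEN", "SPE", "AUC"]].round(3).to_string())
    bench_auc = summary.loc[BENCHMARK_MODEL, "AUC"]
    beat = (summary.loc[list(ENSEMBLE_MODELS), "AUC"] > bench_auc).sum()
    print(f"{beat}/6 ensemble members beat the logistic benchmark "
          f"(AUC {bench_auc:.3f})")

    riv, orv = importance_tables([r for r in results if r.importances is not None])
    riv.round(6).to_csv(OUT / "riv.csv", index_label="variable")
    orv.to_csv(OUT / "orv.csv", index_label="variable")
    top = riv.mean(axis=1).nlargest(5)
    print("top mean-RIV variables:", ", ".join(f"{v} ({s:.1f})" for v, s in top.items()))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
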