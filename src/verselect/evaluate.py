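"""Refitting models on selected variable subsets and sweeping the ten
(rule, k) selection conditions.

The comparison of interest is paired: a refit on a selected subset is run
through the same cross-validation harness, with the same seed and therefore
the same outer-fold partition, as the all-variable baseline — so condition
curves are not confounded by partition noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .config import CVConfig
from .cv import NestedCVResult, run_nested_cv, summarize_metrics
from .features import FEATURE_COLUMNS, feature_array
from .models import ModelSpec, get_model_spec
from .ver import SelectionResult, union_select

SELECTION_KS = (4, 6, 8, 10, 12)


@dataclass
class ConditionReport:
    """Fold-mean performance of a refit on one selection condition."""

    rule: str
    k: int
    n_selected: int
    metrics: pd.Series            # BA/SEN/SPE/AUC means and SDs over folds
    baseline_auc: float | None    # all-variable baseline under the same folds
    result: NestedCVResult


def refit_on_selection(
    features: pd.DataFrame,
    selection: SelectionResult,
    spec: ModelSpec | None = None,
    cv: CVConfig | None = None,
    baseline_auc: float | None = None,
) -> ConditionReport:
    """Re-run the CV harness restricted to the selected columns."""
    if selection.cardinality == 0:
        raise ValueError("cannot refit on an empty selection")
    missing = [v for v in selection.variables if v not in features.columns]
    if missing:
        raise ValueError(f"selected variables absent from the feature matrix: {missing}")
    spec = spec or get_model_spec("lasso")
    X, y, cols = feature_array(features, columns=selection.variables)
    result = run_nested_cv(X, y, cols, spec, cv)
    return ConditionReport(
        rule=selection.rule,
        k=selection.k,
        n_selected=selection.cardinality,
        metrics=summarize_metrics(result.metrics),
        baseline_auc=baseline_auc,
        result=result,
    )


def run_baseline(
    features: pd.DataFrame,
    spec: ModelSpec | None = None,
    cv: CVConfig | None = None,
    columns=None,
) -> NestedCVResult:
    """Fit the refit model on the full 76-variable matrix (the baseline)."""
    spec = spec or get_model_spec("lasso")
    X, y, cols = feature_array(features, columns=columns or FEATURE_COLUMNS)
    return run_nested_cv(X, y, cols, spec, cv)


def sweep_conditions(
    features: pd.DataFrame,
    aggregated: pd.DataFrame,
    spec: ModelSpec | None = None,
    cv: CVConfig | None = None,
    ks: tuple[int, ...] = SELECTION_KS,
) -> tuple[pd.DataFrame, list[ConditionReport]]:
    """Evaluate every (rule, k) condition plus the all-variable baseline.

    Returns a tidy condition table (one row per condition, ``rule='all'``
    for the baseline) and the full per-condition reports.
    """
    spec = spec or get_model_spec("lasso")
    baseline = run_baseline(features, spec, cv)
    baseline_summary = summarize_metrics(baseline.metrics)
    rows = [
        {
            "rule": "all",
            "k": 0,
            "n_selected": len(FEATURE_COLUMNS),
            **baseline_summary.to_dict(),
        }
    ]
    reports: list[ConditionReport] = []
    for rule in ("RIV", "ORV"):
        for k in ks:
            selection = union_select(aggregated, rule, k)
            report = refit_on_selection(
                features, selection, spec, cv, baseline_auc=float(baseline_summary["AUC"])
            )
            reports.append(report)
            rows.append(
                {
                    "rule": rule,
                    "k": k,
                    "n_selected": report.n_selected,
                    **report.metrics.to_dict(),
                }
            )
    return pd.DataFrame(rows), reports


def roc_points(result: NestedCVResult, y: np.ndarray) -> pd.DataFrame:
    """Per-fold ROC curve points from out-of-fold scores (for plotting)."""
    frames = []
    for f, (_, test_idx) in enumerate(result.fold_indices):
        labels = y[test_idx]
        if len(np.unique(labels)) < 2:
            continue
        fpr, tpr, thr = roc_curve(labels, result.oof_scores[test_idx])
        frames.append(
            pd.DataFrame({"fold": f, "fpr": fpr, "tpr": tpr, "threshold": thr})
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["fold", "fpr", "tpr", "threshold"]
    )
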