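"""Nested cross-validation harness.

The outer loop (default 10-fold, stratified) estimates out-of-sample
performance and harvests one raw importance vector per fold; the inner loop
(default 9-fold over the outer-training portion) selects hyperparameters by
mean validation AUC.  Oversampling is applied strictly inside training
partitions — inner-training folds during tuning, the full outer-training
set for the final per-fold refit — so test and validation folds keep the
natural class ratio.  A singleton hyperparameter grid skips the inner loop
entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from .config import CVConfig
from .models import ModelSpec
from .resampling import oversample

logger = logging.getLogger(__name__)

METRIC_NAMES = ("BA", "SEN", "SPE", "AUC")


def evaluate_fold(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> dict:
    """Score one test fold: SEN, SPE, BA at ``threshold``; AUC threshold-free.

    With a single-class fold the AUC is undefined and reported as NaN with
    ``degenerate=True``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    sen = tp / (tp + fn) if (tp + fn) else np.nan
    spe = tn / (tn + fp) if (tn + fp) else np.nan
    ba = (sen + spe) / 2.0
    degenerate = len(np.unique(labels)) < 2
    auc = np.nan if degenerate else float(roc_auc_score(labels, scores))
    return {"BA": ba, "SEN": sen, "SPE": spe, "AUC": auc, "degenerate": degenerate}


@dataclass
class NestedCVResult:
    """Per-model output of the harness: one raw importance vector and one
    metrics row per outer fold, plus the fold index bookkeeping needed for
    leakage audits."""

    model: str
    feature_names: list[str]
    importances: pd.DataFrame | None  # outer folds x features, raw scale
    metrics: pd.DataFrame             # one row per outer fold
    fold_indices: list[tuple[np.ndarray, np.ndarray]]
    oof_scores: np.ndarray            # out-of-fold predicted probabilities


def _positive_proba(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    pos_col = int(np.where(est.classes_ == 1)[0][0])
    return proba[:, pos_col]


def _tune(spec: ModelSpec, X_tr, y_tr, cv: CVConfig, fold_seed: int) -> dict:
    """Inner loop: pick the grid candidate with the best mean validation AUC."""
    candidates = spec.param_candidates()
    if len(candidates) == 1:
        return candidates[0]
    inner = StratifiedKFold(cv.inner_folds, shuffle=True, random_state=fold_seed)
    best_params, best_auc = candidates[0], -np.inf
    for params in candidates:
        aucs = []
        for j, (tr, va) in enumerate(inner.split(X_tr, y_tr)):
            if len(np.unique(y_tr[va])) < 2:
                continue
            X_os, y_os = oversample(
                X_tr[tr], y_tr[tr], cv.oversampler, cv.oversample_ratio,
                seed=fold_seed * 97 + j,
            )
            est = spec.build(params, fold_seed)
            est.fit(X_os, y_os)
            aucs.append(roc_auc_score(y_tr[va], _positive_proba(est, X_tr[va])))
        mean_auc = float(np.mean(aucs)) if aucs else -np.inf
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params
    return best_params


def run_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    spec: ModelSpec,
    cv: CVConfig | None = None,
) -> NestedCVResult:
    """Run the full nested cross-validation for one model.

    Requires at least two subjects of each class per outer fold (enforced by
    stratification); a degenerate test fold is flagged in the metrics and
    excluded from downstream means.
    """
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("nested CV requires both outcome classes present")
    splitter = (
        StratifiedKFold(cv.outer_folds, shuffle=True, random_state=cv.seed)
        if cv.stratified
        else KFold(cv.outer_folds, shuffle=True, random_state=cv.seed)
    )
    importance_rows, metric_rows, fold_indices = [], [], []
    oof = np.full(len(y), np.nan)
    for f, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        fold_seed = cv.seed * 1009 + f + 1
        params = _tune(spec, X[train_idx], y[train_idx], cv, fold_seed)
        X_os, y_os = oversample(
            X[train_idx], y[train_idx], cv.oversampler, cv.oversample_ratio,
            seed=fold_seed,
        )
        est = spec.build(params, fold_seed)
        est.fit(X_os, y_os)
        scores = _positive_proba(est, X[test_idx])
        oof[test_idx] = scores
        row = evaluate_fold(scores, y[test_idx])
        row["fold"] = f
        row["params"] = repr(params)
        metric_rows.append(row)
        fold_indices.append((train_idx.copy(), test_idx.copy()))
        if spec.importance is not None:
            importance_rows.append(spec.importance(est))
    metrics = pd.DataFrame(metric_rows).set_index("fold")
    importances = (
        pd.DataFrame(importance_rows, columns=feature_names)
        if importance_rows
        else None
    )
    return NestedCVResult(
        model=spec.name,
        feature_names=list(feature_names),
        importances=importances,
        metrics=metrics,
        fold_indices=fold_indices,
        oof_scores=oof,
    )


def merge_folds(per_fold: pd.DataFrame) -> pd.Series:
    """Element-wise arithmetic mean of per-fold raw importance vectors."""
    if per_fold is None or len(per_fold) == 0:
        raise ValueError("no valid folds to merge")
    valid = per_fold.dropna(how="all")
    if valid.empty:
        raise ValueError("all folds invalid; nothing to merge")
    return valid.mean(axis=0)


def summarize_metrics(metrics: pd.DataFrame) -> pd.Series:
    """Mean and SD of each metric over non-degenerate outer folds."""
    usable = metrics[~metrics["degenerate"]] if "degenerate" in metrics else metrics
    out = {}
    for name in METRIC_NAMES:
        out[name] = float(usable[name].mean())
        out[f"{name}_sd"] = float(usable[name].std(ddof=1)) if len(usable) > 1 else 0.0
    out["n_folds"] = int(len(usable))
    return pd.Series(out)
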