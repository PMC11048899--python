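"""Nested cross-validation harness: metrics, structure, leakage, importances."""

import numpy as np
import pytest

from verselect.config import CVConfig
from verselect.cv import evaluate_fold, run_nested_cv, summarize_metrics
from verselect.features import feature_array
from verselect.importance import importance_tables
from verselect.models import ENSEMBLE_MODELS, FAST_GRIDS, get_model_spec


def test_evaluate_fold_confusion_arithmetic():
    # 10 positives: 7 scored above threshold; 10 negatives: 6 below
    scores = np.array([0.9] * 7 + [0.1] * 3 + [0.2] * 6 + [0.8] * 4)
    labels = np.array([1] * 10 + [0] * 10)
    m = evaluate_fold(scores, labels)
    assert m["SEN"] == pytest.approx(0.7)
    assert m["SPE"] == pytest.approx(0.6)
    assert m["BA"] == pytest.approx(0.65)
    assert not m["degenerate"]


def test_evaluate_fold_perfect_separation():
    scores = np.array([0.99, 0.98, 0.01, 0.02])
    labels = np.array([1, 1, 0, 0])
    m = evaluate_fold(scores, labels)
    assert m["BA"] == m["SEN"] == m["SPE"] == m["AUC"] == 1.0


def test_evaluate_fold_null_auc_monte_carlo():
    rng = np.random.default_rng(11)
    scores = rng.uniform(size=2000)
    labels = np.concatenate([np.ones(1000, int), np.zeros(1000, int)])
    m = evaluate_fold(scores, labels)
    assert abs(m["AUC"] - 0.5) < 0.04


def test_evaluate_fold_single_class_flagged():
    m = evaluate_fold(np.array([0.2, 0.9]), np.array([1, 1]))
    assert m["degenerate"] and np.isnan(m["AUC"])


def test_structural_contract_and_determinism(planted_features, small_cv):
    X, y, cols = feature_array(planted_features)
    spec = get_model_spec("lasso", FAST_GRIDS)
    res = run_nested_cv(X, y, cols, spec, small_cv)
    assert len(res.fold_indices) == small_cv.outer_folds
    assert res.importances.shape == (small_cv.outer_folds, 76)
    assert len(res.metrics) == small_cv.outer_folds
    res2 = run_nested_cv(X, y, cols, spec, small_cv)
    np.testing.assert_array_equal(res.oof_scores, res2.oof_scores)


def test_no_train_test_leakage(planted_features, small_cv):
    """Index audit: folds partition the cohort and never overlap their
    training data; test folds keep the natural class ratio."""
    X, y, cols = feature_array(planted_features)
    res = run_nested_cv(X, y, cols, get_model_spec("lasso", FAST_GRIDS), small_cv)
    seen = []
    for train_idx, test_idx in res.fold_indices:
        assert len(np.intersect1d(train_idx, test_idx)) == 0
        assert len(train_idx) + len(test_idx) == len(y)
        seen.append(test_idx)
        # stratification keeps the minority fraction close to natural
        frac = y[test_idx].mean()
        assert abs(frac - y.mean()) < 0.05
    all_test = np.concatenate(seen)
    assert len(all_test) == len(y)
    assert len(np.unique(all_test)) == len(y)


def test_inner_loop_selects_from_grid(planted_features):
    X, y, cols = feature_array(planted_features)
    spec = get_model_spec("lasso", {"lasso": {"C": [0.05, 1.0]}})
    cv = CVConfig(outer_folds=3, inner_folds=3, seed=0)
    res = run_nested_cv(X, y, cols, spec, cv)
    chosen = set(res.metrics["params"])
    assert chosen <= {"{'C': 0.05}", "{'C': 1.0}"}


def test_single_class_cohort_rejected(planted_features, small_cv):
    X, y, cols = feature_array(planted_features)
    with pytest.raises(ValueError):
        run_nested_cv(X, np.zeros_like(y), cols, get_model_spec("lasso"), small_cv)


def test_dominant_effect_tops_importance_for_most_models(planted_features, small_cv):
    """With one strong planted effect, the generating extended variable
    should attain the column-max raw importance for at least 5 of the 6
    ensemble members."""
    X, y, cols = feature_array(planted_features)
    results = [
        run_nested_cv(X, y, cols, get_model_spec(name, FAST_GRIDS), small_cv)
        for name in ENSEMBLE_MODELS
    ]
    riv, orv = importance_tables(results)
    top_hits = sum(riv[m].idxmax() == "BUN(S)" for m in riv.columns)
    assert top_hits >= 5
    assert (orv.loc["BUN(S)"] <= 3).sum() >= 5


def test_summarize_skips_degenerate_folds(planted_features, small_cv):
    X, y, cols = feature_array(planted_features)
    res = run_nested_cv(X, y, cols, get_model_spec("lasso", FAST_GRIDS), small_cv)
    summary = summarize_metrics(res.metrics)
    assert 0.0 <= summary["AUC"] <= 1.0
    assert summary["BA"] == pytest.approx((summary["SEN"] + summary["SPE"]) / 2, abs=1e-9)
    assert summary["n_folds"] == small_cv.outer_folds
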