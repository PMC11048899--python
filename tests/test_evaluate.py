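"""Selection refits, condition sweeps, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from verselect.config import CVConfig, GeneratorConfig
from verselect.evaluate import refit_on_selection, run_baseline, sweep_conditions
from verselect.features import FEATURE_COLUMNS, feature_array
from verselect.models import FAST_GRIDS, get_model_spec
from verselect.pipeline import run_pipeline
from verselect.ver import SelectionResult


def test_refit_on_full_selection_equals_baseline(planted_features, small_cv):
    """Restricting to all 76 columns is the identity: the report must match
    the baseline run exactly (paired folds, same seed)."""
    spec = get_model_spec("lasso", FAST_GRIDS)
    baseline = run_baseline(planted_features, spec, small_cv)
    selection = SelectionResult(rule="RIV", k=76, variables=tuple(FEATURE_COLUMNS))
    report = refit_on_selection(planted_features, selection, spec, small_cv)
    np.testing.assert_allclose(
        report.result.oof_scores, baseline.oof_scores, rtol=0, atol=1e-12
    )


def test_refit_rejects_empty_or_unknown_selection(planted_features, small_cv):
    spec = get_model_spec("lasso", FAST_GRIDS)
    with pytest.raises(ValueError):
        refit_on_selection(
            planted_features, SelectionResult("RIV", 1, ()), spec, small_cv
        )
    with pytest.raises(ValueError, match="absent"):
        refit_on_selection(
            planted_features, SelectionResult("RIV", 1, ("NOPE(C)",)), spec, small_cv
        )


def test_paired_folds_between_conditions(planted_features, small_cv):
    spec = get_model_spec("lasso", FAST_GRIDS)
    baseline = run_baseline(planted_features, spec, small_cv)
    selection = SelectionResult("RIV", 2, ("BUN(S)", "BUN(M)", "Hb(S)"))
    report = refit_on_selection(planted_features, selection, spec, small_cv)
    for (tr_a, te_a), (tr_b, te_b) in zip(
        baseline.fold_indices, report.result.fold_indices
    ):
        np.testing.assert_array_equal(te_a, te_b)
        np.testing.assert_array_equal(tr_a, tr_b)


def test_sweep_covers_all_conditions(planted_features, small_cv):
    rng = np.random.default_rng(0)
    fake_raw = pd.DataFrame(
        rng.uniform(size=(76, 6)), index=list(FEATURE_COLUMNS),
        columns=["m1", "m2", "m3", "m4", "m5", "m6"],
    )
    from verselect.importance import compute_orv, compute_riv
    from verselect.ver import aggregate_tables

    riv = fake_raw.apply(compute_riv, axis=0)
    orv = riv.apply(compute_orv, axis=0)
    aggregated = aggregate_tables(riv, orv)
    conditions, reports = sweep_conditions(
        planted_features, aggregated, get_model_spec("lasso", FAST_GRIDS), small_cv
    )
    assert len(conditions) == 11  # baseline + 2 rules x 5 cutoffs
    assert conditions.iloc[0]["rule"] == "all"
    assert sorted(set(conditions["k"]) - {0}) == [4, 6, 8, 10, 12]
    assert len(reports) == 10
    assert all(r.baseline_auc == pytest.approx(conditions.iloc[0]["AUC"]) for r in reports)
    assert (conditions["n_selected"].iloc[1:] <= 36).all()  # <= 3k


def test_pipeline_end_to_end_and_determinism(tmp_path):
    gen = GeneratorConfig(n_subjects=120, class_ratio=0.2, seed=21)
    cv = CVConfig(outer_folds=4, inner_folds=3, seed=21)
    kwargs = dict(
        generator=gen, cv=cv, grids=FAST_GRIDS,
        models=("lasso", "rf"), ks=(2, 4),
    )
    bundle = run_pipeline(**kwargs, outdir=tmp_path / "run")
    assert bundle.riv.shape == (76, 2)
    assert set(bundle.aggregated.columns) == {
        "RIV-AMA", "RIV-GMA", "RIV-MA", "ORV-AMA", "ORV-RMA", "ORV-BCA",
    }
    assert len(bundle.conditions) == 1 + 2 * 2
    for name in (
        "records.csv", "panel.csv", "features.csv", "riv.csv", "orv.csv",
        "aggregated.csv", "rankings.csv", "conditions.csv", "manifest.json",
        "roc_points.csv", "model_metrics.csv",
    ):
        assert (tmp_path / "run" / name).exists(), name
    bundle2 = run_pipeline(**kwargs)
    pd.testing.assert_frame_equal(bundle.conditions, bundle2.conditions)
    pd.testing.assert_frame_equal(bundle.aggregated, bundle2.aggregated)


def test_pipeline_input_validation():
    with pytest.raises(ValueError):
        run_pipeline()  # neither generator nor records
    with pytest.raises(ValueError):
        run_pipeline(
            generator=GeneratorConfig(seed=0), records=pd.DataFrame()
        )
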