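"""The model zoo: six importance-scoring classifiers plus a benchmark.

Every ensemble member must expose a model-native feature-importance score,
since the whole scheme runs on importance profiles rather than predictions
alone.  The registry pairs each member with

* a constructor (hyperparameters + seed -> estimator),
* a hyperparameter grid (config, not code — two presets are bundled), and
* an importance extractor mapping a fitted estimator to one non-negative
  score per feature.

Members and their importance kinds:

==============  ============================================  =================
name            estimator                                     importance
==============  ============================================  =================
rf              RandomForestClassifier                        impurity decrease
extra_trees     ExtraTreesClassifier                          impurity decrease
gbdt            GradientBoostingClassifier                    impurity decrease
xgboost         XGBClassifier                                 split gain
lightgbm        LGBMClassifier                                split gain
lasso           L1 logistic regression (standardised inputs)  |coefficient|
lgr (benchmark) plain logistic regression                     (none; excluded
                                                              from ensembles)
==============  ============================================  =================

The unpenalised logistic benchmark runs through the identical
cross-validation harness but contributes no importance column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier


@dataclass(frozen=True)
class ModelSpec:
    """One member of the zoo: how to build it, tune it, and read importances."""

    name: str
    build: Callable[[Mapping, int], object]
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    importance: Callable[[object], np.ndarray] | None = None
    is_benchmark: bool = False

    def __post_init__(self) -> None:
        if not self.is_benchmark and self.importance is None:
            raise ValueError(
                f"ensemble member {self.name!r} must declare an importance extractor"
            )

    def param_candidates(self) -> list[dict]:
        """Cartesian product of the grid (a singleton grid yields one dict)."""
        items = sorted(self.grid.items())
        candidates: list[dict] = [{}]
        for key, values in items:
            candidates = [{**c, key: v} for c in candidates for v in values]
        return candidates


def _tree_importance(est) -> np.ndarray:
    return np.asarray(est.feature_importances_, dtype=float)


def _coef_importance(est) -> np.ndarray:
    clf = est.named_steps["clf"] if isinstance(est, Pipeline) else est
    return np.abs(np.asarray(clf.coef_, dtype=float).ravel())


def _build_rf(params: Mapping, seed: int):
    kwargs = {"n_estimators": 300, "max_features": "sqrt", **params}
    return RandomForestClassifier(random_state=seed, n_jobs=1, **kwargs)


def _build_extra_trees(params: Mapping, seed: int):
    kwargs = {"n_estimators": 300, "max_features": "sqrt", **params}
    return ExtraTreesClassifier(random_state=seed, n_jobs=1, **kwargs)


def _build_gbdt(params: Mapping, seed: int):
    kwargs = {"n_estimators": 120, "learning_rate": 0.1, "max_depth": 2, **params}
    return GradientBoostingClassifier(random_state=seed, **kwargs)


def _build_xgboost(params: Mapping, seed: int):
    kwargs = {"n_estimators": 150, "learning_rate": 0.1, "max_depth": 3, **params}
    return XGBClassifier(
        tree_method="hist",
        importance_type="gain",
        eval_metric="logloss",
        n_jobs=1,
        random_state=seed,
        **kwargs,
    )


def _build_lightgbm(params: Mapping, seed: int):
    kwargs = {"n_estimators": 150, "learning_rate": 0.1, "num_leaves": 15, **params}
    return LGBMClassifier(
        importance_type="gain",
        n_jobs=1,
        random_state=seed,
        verbosity=-1,
        **kwargs,
    )


def _build_lasso(params: Mapping, seed: int):
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=params.get("C", 0.2),
        max_iter=5000, random_state=seed,
    )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _build_lgr(params: Mapping, seed: int):
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


#: default grids: a small search per member (inner loop tunes these)
DEFAULT_GRIDS: dict[str, dict] = {
    "rf": {"max_features": ["sqrt", 0.2]},
    "extra_trees": {"max_features": ["sqrt", 0.2]},
    "gbdt": {"max_depth": [2, 3]},
    "xgboost": {"max_depth": [2, 3]},
    "lightgbm": {"num_leaves": [7, 15]},
    "lasso": {"C": [0.05, 0.2, 1.0]},
    "lgr": {},
}

#: singleton grids: no inner tuning and lighter ensembles — used for
#: Monte-Carlo replicate studies where many cohorts are fit in sequence
FAST_GRIDS: dict[str, dict] = {
    "rf": {"n_estimators": [100]},
    "extra_trees": {"n_estimators": [100]},
    "gbdt": {"n_estimators": [50]},
    "xgboost": {"n_estimators": [80]},
    "lightgbm": {"n_estimators": [80]},
    "lasso": {},
    "lgr": {},
}

_BUILDERS: dict[str, tuple[Callable, Callable | None, bool]] = {
    "rf": (_build_rf, _tree_importance, False),
    "extra_trees": (_build_extra_trees, _tree_importance, False),
    "gbdt": (_build_gbdt, _tree_importance, False),
    "xgboost": (_build_xgboost, _tree_importance, False),
    "lightgbm": (_build_lightgbm, _tree_importance, False),
    "lasso": (_build_lasso, _coef_importance, False),
    "lgr": (_build_lgr, None, True),
}

#: canonical column order for importance tables
ENSEMBLE_MODELS: tuple[str, ...] = (
    "rf", "lasso", "xgboost", "lightgbm", "gbdt", "extra_trees"
)
BENCHMARK_MODEL = "lgr"


def get_model_spec(name: str, grids: Mapping[str, Mapping] | None = None) -> ModelSpec:
    """Look up a member by name; ``grids`` overrides the bundled defaults."""
    if name not in _BUILDERS:
        raise KeyError(
            f"unknown model {name!r}; expected one of {sorted(_BUILDERS)}"
        )
    build, importance, is_benchmark = _BUILDERS[name]
    grid = (grids or DEFAULT_GRIDS).get(name, {})
    return ModelSpec(
        name=name, build=build, grid=grid, importance=importance,
        is_benchmark=is_benchmark,
    )
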