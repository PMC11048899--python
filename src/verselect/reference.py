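"""Bundled reference worked example.

A small set of tables from a six-model importance analysis of the 76
extended screening variables accompanies the package:

* ``reference_riv`` / ``reference_orv`` — the RIV and ORV profiles of the
  first 12 extended variables (BF, BMI and BUN with their C/M/S/D
  statistics) across six importance-scoring models;
* ``reference_aggregated`` — the six VER aggregates of those profiles;
* ``reference_rankings`` — the top-12 variable ranking per aggregate over
  the full 76-variable panel;
* ``reference_selections`` — the top-k union selections (k = 4, 6, 8, 10,
  12) derived from those rankings;
* ``reference_metrics`` — BA/SEN/SPE/AUC summaries (mean and SD over outer
  folds) for the six models and the logistic benchmark.

These serve as regression fixtures for the aggregation and selection
operators: the aggregates and selections are re-derivable from the profile
tables, so the arithmetic can be checked end to end without any cohort
data.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_DATA = resources.files("verselect") / "data"


def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, **kwargs)


def reference_riv() -> pd.DataFrame:
    """12 variables x 6 models, RIV scale."""
    return _read_csv("reference_riv.csv", index_col="variable")


def reference_orv() -> pd.DataFrame:
    """12 variables x 6 models, ORV scale (integer ranks within 76)."""
    return _read_csv("reference_orv.csv", index_col="variable").astype(int)


def reference_aggregated() -> pd.DataFrame:
    """Expected VER aggregates of the reference profiles (2-dp values)."""
    return _read_csv("reference_aggregated.csv", index_col="variable")


def reference_rankings() -> dict[str, list[str]]:
    """Top-12 variable names per aggregate, as ordered lists."""
    frame = _read_csv("reference_rankings.csv", index_col="rank")
    return {col: frame[col].tolist() for col in frame.columns}


def reference_selections() -> dict[str, dict[int, list[str]]]:
    """Expected top-k union selections per scale: rule -> {k -> variables}."""
    raw = json.loads((_DATA / "reference_selections.json").read_text())
    return {rule: {int(k): v for k, v in per_k.items()} for rule, per_k in raw.items()}


def reference_metrics() -> pd.DataFrame:
    """Fold-mean BA/SEN/SPE/AUC (with SDs) for six models plus the benchmark."""
    return _read_csv("reference_metrics.csv", index_col="model")
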