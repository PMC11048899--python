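"""Extended-variable construction.

Each of the 19 base measurements is expanded into four statistics over the
two predictor exams (values v1, v2):

    C = v2                       (closest: the more recent exam)
    M = (v1 + v2) / 2            (mean)
    S = sqrt(((v1-M)^2 + (v2-M)^2) / (2-1))   (sample SD; equals |D|/sqrt(2))
    D = v2 - v1                  (difference)

yielding the 76-column predictor matrix.  No imputation is performed: a
missing measurement is an error naming the subject and variable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .variables import STATISTICS, VARIABLE_CODES, extended_name

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = tuple(
    extended_name(code, stat) for code in VARIABLE_CODES for stat in STATISTICS
)


def extend_variables(panel: pd.DataFrame) -> pd.DataFrame:
    """Expand a longitudinal panel into the extended feature matrix.

    ``panel`` must carry ``<code>_1`` and ``<code>_2`` for every base
    variable plus ``subject_id`` and ``Y``; the result has one column per
    extended variable (C, M, S, D per base variable) plus ``subject_id``
    and ``Y``.
    """
    for code in VARIABLE_CODES:
        for suffix in ("_1", "_2"):
            col = f"{code}{suffix}"
            if col not in panel.columns:
                raise ValueError(f"panel is missing measurement column {col!r}")
            if panel[col].isna().any():
                bad = panel.loc[panel[col].isna(), "subject_id"].tolist()
                raise ValueError(
                    f"missing {code} (exam{suffix[1]}) for subjects {bad}; "
                    "no imputation is performed"
                )

    out = pd.DataFrame({"subject_id": panel["subject_id"].to_numpy()})
    for code in VARIABLE_CODES:
        v1 = panel[f"{code}_1"].to_numpy(dtype=float)
        v2 = panel[f"{code}_2"].to_numpy(dtype=float)
        m = (v1 + v2) / 2.0
        out[extended_name(code, "C")] = v2
        out[extended_name(code, "M")] = m
        out[extended_name(code, "S")] = np.sqrt((v1 - m) ** 2 + (v2 - m) ** 2)
        out[extended_name(code, "D")] = v2 - v1
    out["Y"] = panel["Y"].to_numpy(dtype=int)

    constant = [c for c in FEATURE_COLUMNS if out[c].nunique() <= 1]
    if constant:
        logger.warning("constant extended columns (may break RIV scaling): %s", constant)
    return out


def feature_array(features: pd.DataFrame, columns=None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature matrix into (X, y, column names) for model fitting."""
    cols = list(columns) if columns is not None else list(FEATURE_COLUMNS)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature matrix is missing columns {missing}")
    X = features[cols].to_numpy(dtype=float)
    y = features["Y"].to_numpy(dtype=int)
    return X, y, cols


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
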