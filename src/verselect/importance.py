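"""Importance rescaling: raw scores -> RIV -> ORV.

RIV (relative importance value) is a per-model min-max rescaling of raw
importances to [0, 100]: the most important variable scores 100 and the
least 0.  It is invariant to positive affine transforms of the raw scores.

ORV (ordinal ranking value) ranks the RIVs descending, rank 1 = best.
Tied values all receive the *worst* (largest) position of their tied block,
so e.g. a run of zero-importance variables at the bottom of a 76-variable
column all carry rank 76.  ORV is invariant to any strictly monotone
transform of the raw scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cv import NestedCVResult, merge_folds


def compute_riv(raw: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Min-max rescale a raw importance vector to [0, 100].

    A constant vector has no defined scaling; that usually means the model
    degenerated (e.g. every coefficient shrunk to zero) and should be
    inspected rather than silently rescaled.
    """
    values = np.asarray(raw, dtype=float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        raise ValueError(
            "constant importance vector: RIV scaling is undefined; inspect the "
            "degenerate model before aggregating"
        )
    riv = 100.0 * (values - lo) / (hi - lo)
    if isinstance(raw, pd.Series):
        return pd.Series(riv, index=raw.index)
    return riv


def compute_orv(riv: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rank RIVs descending with the worst-of-block tie rule (integer 1..n)."""
    values = np.asarray(riv, dtype=float)
    ranks = rankdata(-values, method="max").astype(int)
    if isinstance(riv, pd.Series):
        return pd.Series(ranks, index=riv.index)
    return ranks


def importance_tables(
    results: list[NestedCVResult], merge_order: str = "merge_then_scale"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the (variables x models) RIV and ORV tables from CV results.

    ``merge_order`` controls when per-fold vectors are rescaled:

    * ``"merge_then_scale"`` (default): average raw importances over folds,
      then min-max to RIV, then rank to ORV — so ORVs are integers;
    * ``"scale_then_merge"``: rescale each fold to RIV first, then average.

    Benchmark results (no importances) are skipped.
    """
    if merge_order not in ("merge_then_scale", "scale_then_merge"):
        raise ValueError(f"unknown merge_order {merge_order!r}")
    riv_cols: dict[str, pd.Series] = {}
    for res in results:
        if res.importances is None:
            continue
        if merge_order == "merge_then_scale":
            merged = merge_folds(res.importances)
            riv_cols[res.model] = compute_riv(merged)
        else:
            per_fold = res.importances.apply(
                lambda row: compute_riv(row.to_numpy()), axis=1, result_type="broadcast"
            )
            riv_cols[res.model] = merge_folds(per_fold)
    if not riv_cols:
        raise ValueError("no ensemble member produced importances")
    riv = pd.DataFrame(riv_cols)
    orv = riv.apply(compute_orv, axis=0)
    return riv, orv
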