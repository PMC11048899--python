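"""Variable ensemble rules (VERs): rank aggregation across models.

Each variable carries one importance value per model, either on the RIV
scale (ratio, 0-100, larger = more important) or the ORV scale (ordinal
rank, 1 = most important).  Five aggregation rules combine the per-model
values into a single score:

* AMA — arithmetic mean,
* GMA — geometric mean (any zero input collapses to zero),
* MA  — maximum,
* RMA — median,
* BCA — the most frequent rank; if every model assigned a distinct rank,
  the worst (largest) rank is taken, and a tie between modal ranks is also
  resolved to the worst — the "worst-case" reading of modal aggregation.

The scale determines which rules apply: RIV is aggregated with AMA, GMA and
MA; ORV with AMA, RMA and BCA.  Feature selection then takes, for one scale,
the union of the top-k variables across its three aggregates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RIV_AGGREGATES = ("AMA", "GMA", "MA")
ORV_AGGREGATES = ("AMA", "RMA", "BCA")
RULE_COLUMNS = tuple(f"RIV-{a}" for a in RIV_AGGREGATES) + tuple(
    f"ORV-{a}" for a in ORV_AGGREGATES
)


def _check_nonempty(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("aggregation over an empty value set is undefined")
    if not np.all(np.isfinite(values)):
        raise ValueError("aggregation requires finite values")
    return values


def ama(values: Sequence[float]) -> float:
    """Arithmetic mean."""
    return float(np.mean(_check_nonempty(values)))


def gma(values: Sequence[float]) -> float:
    """Geometric mean; zero-absorbing, undefined for negative inputs."""
    values = _check_nonempty(values)
    if np.any(values < 0):
        raise ValueError("geometric mean is undefined for negative importances")
    if np.any(values == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(values))))


def ma(values: Sequence[float]) -> float:
    """Maximum."""
    return float(np.max(_check_nonempty(values)))


def rma(values: Sequence[float]) -> float:
    """Median (mean of the central pair for an even number of models)."""
    return float(np.median(_check_nonempty(values)))


def bca(values: Sequence[float]) -> int:
    """Modal rank with worst-case fallbacks.

    Returns the most frequent rank.  If all ranks are distinct the worst
    (largest) rank is returned; a tie between equally frequent modes is also
    resolved to the worst modal rank.
    """
    values = _check_nonempty(values)
    if not np.all(values == np.round(values)):
        raise ValueError("BCA operates on integer ordinal ranks")
    ints = [int(v) for v in values]
    counts = Counter(ints)
    max_freq = max(counts.values())
    if max_freq == 1:
        return max(ints)
    return max(v for v, c in counts.items() if c == max_freq)


_RULE_FUNCS = {"AMA": ama, "GMA": gma, "MA": ma, "RMA": rma, "BCA": bca}


def aggregate_tables(riv_table: pd.DataFrame, orv_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate (variables x models) RIV and ORV tables with all six rules.

    Returns a variables-indexed frame with columns ``RIV-AMA``, ``RIV-GMA``,
    ``RIV-MA``, ``ORV-AMA``, ``ORV-RMA``, ``ORV-BCA``.  Both inputs must
    cover the same variable set.
    """
    sym_diff = set(riv_table.index).symmetric_difference(orv_table.index)
    if sym_diff:
        raise ValueError(
            f"RIV and ORV tables cover different variables: {sorted(sym_diff)}"
        )
    orv_table = orv_table.loc[riv_table.index]
    out = pd.DataFrame(index=riv_table.index)
    for agg in RIV_AGGREGATES:
        out[f"RIV-{agg}"] = [
            _RULE_FUNCS[agg](row) for row in riv_table.to_numpy(dtype=float)
        ]
    for agg in ORV_AGGREGATES:
        out[f"ORV-{agg}"] = [
            _RULE_FUNCS[agg](row) for row in orv_table.to_numpy(dtype=float)
        ]
    return out


def rank_positions(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Derive rank positions (1 = most important) from aggregated values.

    RIV rules rank descending (larger value = better); ORV rules ascending.
    Tied values share the *best* position of their block, so a top-k cut at
    a straddling block keeps the whole block (conservative superset).
    """
    ranks = pd.DataFrame(index=aggregated.index)
    for col in aggregated.columns:
        values = aggregated[col].to_numpy(dtype=float)
        key = -values if col.startswith("RIV") else values
        ranks[col] = rankdata(key, method="min").astype(int)
    return ranks


def ranking_table(aggregated: pd.DataFrame, n_top: int = 12) -> pd.DataFrame:
    """Top-``n_top`` variable names per rule (display layout; ties broken
    alphabetically for a deterministic listing)."""
    ranks = rank_positions(aggregated)
    table = {}
    for col in aggregated.columns:
        order = sorted(aggregated.index, key=lambda v: (ranks.loc[v, col], v))
        table[col] = order[:n_top]
    return pd.DataFrame(table, index=pd.RangeIndex(1, n_top + 1, name="rank"))


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the top-k union over one scale's three aggregates."""

    rule: str                 # "RIV" or "ORV"
    k: int
    variables: tuple[str, ...]

    @property
    def cardinality(self) -> int:
        return len(self.variables)


def _scale_aggregates(rule: str) -> tuple[str, ...]:
    if rule == "RIV":
        return tuple(f"RIV-{a}" for a in RIV_AGGREGATES)
    if rule == "ORV":
        return tuple(f"ORV-{a}" for a in ORV_AGGREGATES)
    raise ValueError(f"rule must be 'RIV' or 'ORV', got {rule!r}")


def union_select(aggregated: pd.DataFrame, rule: str, k: int) -> SelectionResult:
    """Union of the top-k variables across the rule's three aggregates.

    Variables are listed in discovery order: scanning rank positions 1..k
    and, within a position, the aggregates in canonical order.  A tied block
    straddling position k is included in full.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(aggregated):
        raise ValueError(f"k={k} exceeds the {len(aggregated)} ranked variables")
    cols = _scale_aggregates(rule)
    ranks = rank_positions(aggregated[list(cols)])
    ordered: list[str] = []
    for pos in range(1, k + 1):
        for col in cols:
            block = sorted(ranks.index[ranks[col] == pos])
            for var in block:
                if var not in ordered:
                    ordered.append(var)
    return SelectionResult(rule=rule, k=k, variables=tuple(ordered))


def union_from_rank_lists(
    columns: Mapping[str, Sequence[str]], rule: str, k: int
) -> SelectionResult:
    """Top-k union when only ordered rank lists (not values) are available,
    e.g. a published top-12 ranking table."""
    cols = _scale_aggregates(rule)
    missing = [c for c in cols if c not in columns]
    if missing:
        raise ValueError(f"rank lists missing aggregates {missing}")
    if any(k > len(columns[c]) for c in cols):
        raise ValueError(f"k={k} exceeds the depth of the supplied rank lists")
    ordered: list[str] = []
    for pos in range(k):
        for col in cols:
            var = columns[col][pos]
            if var not in ordered:
                ordered.append(var)
    return SelectionResult(rule=rule, k=k, variables=tuple(ordered))
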