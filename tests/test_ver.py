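"""Variable-ensemble-rule aggregation and top-k union selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from verselect.reference import reference_orv, reference_riv
from verselect.ver import (
    aggregate_tables,
    ama,
    bca,
    gma,
    ma,
    rank_positions,
    rma,
    union_from_rank_lists,
    union_select,
)

# six-model profiles of single variables, and their aggregate values
BF_C_RIV = (24.00, 1.41, 0.22, 9.22, 10.43, 3.78)
BF_C_ORV = (18, 70, 70, 25, 39, 34)
BUN_S_RIV = (99.03, 100.00, 53.95, 100.00, 94.22, 100.00)
BUN_S_ORV = (2, 1, 3, 1, 2, 1)
BUN_M_ORV = (2, 26, 4, 3, 6, 11)


@pytest.mark.parametrize(
    "func,values,expected",
    [
        (ama, BF_C_RIV, 8.18),
        (gma, BF_C_RIV, 3.73),
        (ma, BF_C_RIV, 24.00),
        (ama, BUN_S_RIV, 91.20),
        (ma, BUN_S_RIV, 100.00),
        (ama, BF_C_ORV, 42.67),
        (rma, BF_C_ORV, 36.50),
        (rma, BUN_S_ORV, 1.50),
    ],
)
def test_aggregates_on_reference_profiles(func, values, expected):
    assert func(values) == pytest.approx(expected, abs=0.005)


def test_gma_zero_absorbing_and_simple_cases():
    assert gma((23.37, 13.20, 0.00, 9.30, 14.07, 0.43)) == 0.0
    assert gma((4.0, 9.0)) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        gma((4.0, -1.0))


def test_ama_rma_ma_simple_cases():
    assert ama((5.0,)) == 5.0
    assert ama((3.0, 3.0, 3.0)) == 3.0
    assert rma((1.0, 2.0, 3.0)) == 2.0
    assert ma((7.0,)) == 7.0
    for func in (ama, gma, ma, rma, bca):
        with pytest.raises(ValueError):
            func(())


def test_bca_repeated_rank_wins():
    assert bca(BF_C_ORV) == 70


def test_bca_all_distinct_falls_back_to_worst():
    assert bca(BUN_M_ORV) == 26


def test_bca_tied_modes_resolve_to_worst():
    assert bca((1, 1, 2, 2, 3)) == 2


def test_bca_requires_integer_ranks():
    with pytest.raises(ValueError, match="integer"):
        bca((1.5, 2.0, 2.0))


def test_aggregate_tables_pairing_and_shape():
    agg = aggregate_tables(reference_riv(), reference_orv())
    assert list(agg.columns) == [
        "RIV-AMA", "RIV-GMA", "RIV-MA", "ORV-AMA", "ORV-RMA", "ORV-BCA",
    ]
    assert agg.loc["BF(C)", "RIV-AMA"] == pytest.approx(8.18, abs=0.005)
    assert agg.loc["BF(C)", "ORV-BCA"] == 70
    assert agg.loc["BUN(M)", "ORV-BCA"] == 26


def test_aggregate_tables_variable_mismatch_rejected():
    riv = reference_riv()
    with pytest.raises(ValueError, match="BUN\\(D\\)"):
        aggregate_tables(riv, reference_orv().drop(index="BUN(D)"))


def test_single_model_tables_reduce_to_input():
    riv = reference_riv()[["RF"]]
    orv = reference_orv()[["RF"]]
    agg = aggregate_tables(riv, orv)
    for col in ("RIV-AMA", "RIV-GMA", "RIV-MA"):
        np.testing.assert_allclose(agg[col], riv["RF"], rtol=1e-9)
    for col in ("ORV-AMA", "ORV-RMA", "ORV-BCA"):
        np.testing.assert_allclose(agg[col], orv["RF"])


def test_column_permutation_invariance():
    riv, orv = reference_riv(), reference_orv()
    perm = ["LightGBM", "RF", "CatBoost", "Lasso", "MARS", "XGBoost"]
    pd.testing.assert_frame_equal(
        aggregate_tables(riv, orv), aggregate_tables(riv[perm], orv[perm])
    )


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**16))
def test_gma_ama_ma_ordering(seed):
    """GMA <= AMA <= MA for non-negative inputs (AM-GM and max bounds)."""
    rng = np.random.default_rng(seed)
    riv = pd.DataFrame(
        rng.uniform(0, 100, size=(15, 6)), index=[f"v{i}" for i in range(15)]
    )
    orv = riv.rank(ascending=False, method="max").astype(int)
    agg = aggregate_tables(riv, orv)
    assert (agg["RIV-GMA"] <= agg["RIV-AMA"] + 1e-9).all()
    assert (agg["RIV-AMA"] <= agg["RIV-MA"] + 1e-9).all()


def _toy_aggregated():
    values = pd.DataFrame(
        {
            "RIV-AMA": [90.0, 80.0, 70.0, 60.0],
            "RIV-GMA": [85.0, 65.0, 75.0, 55.0],
            "RIV-MA": [99.0, 98.0, 50.0, 97.0],
        },
        index=["w", "x", "y", "z"],
    )
    return values


def test_union_select_discovery_order_and_content():
    sel = union_select(_toy_aggregated(), "RIV", 2)
    # rank1: w (AMA), w (GMA), w (MA); rank2: x (AMA), y (GMA), x (MA)
    assert sel.variables == ("w", "x", "y")
    assert sel.cardinality == 3


def test_union_select_monotone_in_k():
    agg = _toy_aggregated()
    previous: set = set()
    for k in (1, 2, 3, 4):
        current = set(union_select(agg, "RIV", k).variables)
        assert previous <= current
        previous = current


def test_union_of_identical_rankings_has_k_members():
    base = pd.Series([40.0, 30.0, 20.0, 10.0], index=list("abcd"))
    agg = pd.DataFrame({"RIV-AMA": base, "RIV-GMA": base, "RIV-MA": base})
    for k in (1, 2, 3):
        assert union_select(agg, "RIV", k).cardinality == k


def test_union_select_tied_block_included_whole():
    agg = pd.DataFrame(
        {
            "RIV-AMA": [50.0, 50.0, 10.0],
            "RIV-GMA": [50.0, 50.0, 10.0],
            "RIV-MA": [50.0, 50.0, 10.0],
        },
        index=["a", "b", "c"],
    )
    sel = union_select(agg, "RIV", 1)
    assert set(sel.variables) == {"a", "b"}


def test_union_select_validates_k():
    agg = _toy_aggregated()
    with pytest.raises(ValueError):
        union_select(agg, "RIV", 0)
    with pytest.raises(ValueError):
        union_select(agg, "RIV", 5)
    with pytest.raises(ValueError):
        union_select(agg, "XYZ", 2)


def test_rank_positions_directions():
    agg = pd.DataFrame(
        {"RIV-AMA": [10.0, 30.0, 20.0], "ORV-RMA": [3.0, 1.0, 2.0]},
        index=["a", "b", "c"],
    )
    ranks = rank_positions(agg)
    assert ranks["RIV-AMA"].tolist() == [3, 1, 2]  # larger value = better
    assert ranks["ORV-RMA"].tolist() == [3, 1, 2]  # smaller value = better


def test_union_from_rank_lists_requires_all_aggregates():
    with pytest.raises(ValueError):
        union_from_rank_lists({"RIV-AMA": ["a"], "RIV-GMA": ["a"]}, "RIV", 1)
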