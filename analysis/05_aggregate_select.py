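"""Aggregate the importance profiles with the five VERs and select features.

Applies the scale-appropriate rules (RIV: AMA/GMA/MA; ORV: AMA/RMA/BCA),
derives the top-12 ranking table, and forms the ten top-k union selections
(k = 4, 6, 8, 10, 12 per scale).

Run after 04:  python analysis/05_aggregate_select.py
"""

import json
from pathlib import Path

import pandas as pd

from verselect.ver import aggregate_tables, rank_positions, ranking_table, union_select

OUT = Path("results")


def main() -> None:
    riv = pd.read_csv(OUT / "riv.csv", index_col="variable")
    orv = pd.read_csv(OUT / "orv.csv", index_col="variable")
    aggregated = aggregate_tables(riv, orv)
    aggregated.round(6).to_csv(OUT / "aggregated.csv", index_label="variable")
    rank_positions(aggregated).to_csv(OUT / "rank_positions.csv", index_label="variable")
    rankings = ranking_table(aggregated)
    rankings.to_csv(OUT / "rankings.csv")
    print("top-5 of each aggregate:")
    print(rankings.head(5).to_string())

    selections = {}
    for rule in ("RIV", "ORV"):
        selections[rule] = {}
        for k in (4, 6, 8, 10, 12):
            sel = union_select(aggregated, rule, k)
            selections[rule][k] = list(sel.variables)
            print(f"{rule} top-{k} union: {sel.cardinality} variables")
    (OUT / "selections.json").write_text(json.dumps(selections, indent=2))


if __name__ == "__main__":
    main()
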