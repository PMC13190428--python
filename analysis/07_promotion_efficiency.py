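#!/usr/bin/env python
"""Promotion indices and spatial conversion efficiency per spatial type.

Combines each unit's activity intensity with its factor scores weighted
by the activity-specific attribution-gain weights, aggregates the
clipped contributions by spatial type, normalises to promotion-index
shares, and divides by area shares to obtain conversion efficiency
(values above 1 = the type promotes activity beyond its footprint).
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "corridor"

from corridorpa import io as cio
from corridorpa.promotion import conversion_efficiency, promotion_index
from corridorpa.synthetic import ACTIVITIES


def main() -> None:
    grid = cio.read_grid(OUT / "grid.geojson", OUT / "factors.csv")
    screening = pd.read_csv(OUT / "screening.csv")
    retained = screening.loc[screening["retained"], "factor"].tolist()
    intensity = pd.read_csv(OUT / "intensity.csv").pivot(
        index="unit_id", columns="activity", values="intensity")
    types = pd.read_csv(OUT / "types.csv", index_col="unit_id")["type"]
    areas = (types.value_counts() * grid.area_km2).to_dict()

    tables = []
    for act in ACTIVITIES:
        omega = pd.read_csv(OUT / f"importance_{act}.csv",
                            index_col="factor")["weight"]
        pt = promotion_index(intensity[act], grid.factors[retained],
                             omega, types, activity=act)
        pt = conversion_efficiency(pt, areas)
        tables.append(pt.table.assign(activity=act))
        best = pt.efficiency.idxmax()
        print(f"{act}: index shares "
              f"{ {k: round(v, 3) for k, v in pt.index_shares.items()} }; "
              f"max conversion efficiency in '{best}' "
              f"({pt.efficiency[best]:.2f})")
    pd.concat(tables).to_csv(OUT / "promotion.csv", float_format="%.9g")


if __name__ == "__main__":
    main()
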