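"""Promotion index and spatial conversion efficiency.

For one activity, each unit contributes a promotion mass

    c_i = P_i * sum_j S_ij * omega_j        (clipped at 0)

where P_i is the unit's activity intensity, S_ij its standardised score
on retained factor j, and omega_j the activity-specific attribution-gain
weight.  Summing over the units of each spatial type and normalising
gives the promotion index I_t (a share over types); dividing by the
type's area share gives the conversion efficiency E_t = I_t / a_t, where
E_t > 1 means the type promotes activity beyond its spatial footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd


@dataclass
class PromotionTable:
    table: pd.DataFrame   # index type: mass, index, area_share, efficiency
    activity: str

    @property
    def index_shares(self) -> pd.Series:
        return self.table["index"]

    @property
    def efficiency(self) -> pd.Series:
        return self.table["efficiency"]


def promotion_index(P: pd.Series, S: pd.DataFrame, omega: pd.Series,
                    types: pd.Series, activity: str = "",
                    clip_negative: bool = True) -> PromotionTable:
    """Per-type promotion masses and normalised indices.

    ``S`` is standardised internally (z-scores per factor), so negative
    unit contributions are possible; by default they are clipped at zero
    before aggregation so the index stays a share (an unclipped mode is
    available for sensitivity).
    """
    if not np.isclose(omega.sum(), 1.0):
        raise ValueError("factor weights must be normalised to sum 1")
    if (P < 0).any():
        raise ValueError("intensities must be nonnegative")
    common = P.index
    if not (S.index.equals(common) and types.index.equals(common)):
        raise ValueError("unit ids of P, S and types must align")
    sd = S.std(ddof=0).replace(0, 1.0)
    Z = (S - S.mean()) / sd
    score = Z[omega.index].to_numpy() @ omega.to_numpy()
    contrib = P.to_numpy(dtype=float) * score
    if clip_negative:
        contrib = np.clip(contrib, 0.0, None)
    if np.all(contrib == 0):
        raise ValueError("all unit contributions are zero; promotion index undefined")
    mass = pd.Series(contrib, index=common).groupby(types).sum()
    table = pd.DataFrame({"mass": mass})
    table["index"] = table["mass"] / table["mass"].sum()
    table.index.name = "type"
    return PromotionTable(table=table, activity=activity)


def conversion_efficiency(promo: PromotionTable,
                          areas: Mapping[str, float]) -> PromotionTable:
    """Attach area shares and efficiency E_t = I_t / a_t to the table."""
    t = promo.table
    missing = [ty for ty in t.index if ty not in areas]
    if missing:
        raise ValueError(f"missing areas for types: {missing}")
    a = pd.Series({ty: float(areas[ty]) for ty in t.index})
    if (a <= 0).any():
        raise ValueError("type areas must be positive")
    t = t.copy()
    t["area_share"] = a / a.sum()
    t["efficiency"] = t["index"] / t["area_share"]
    return PromotionTable(table=t, activity=promo.activity)
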