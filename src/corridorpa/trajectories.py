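"""GPS trajectory cleaning and grid-cell activity intensity.

Cleaning follows the usual quality-control cascade for fitness-app
tracks: drop records shorter than five minutes (test uploads), drop
records whose mean pace is implausible for the tagged activity, and drop
records containing a positioning jump (a segment whose implied speed
exceeds a teleport limit).  Cleaned tracks are then rasterised into
per-unit, per-activity intensity

    I_A = sum of within-cell activity time / A        [s * km^-2]

i.e. cumulative activity time per unit area, which equals N*d/(v*A) when
each of N occurrences of length d at speed v lies within one cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .synthetic import ACTIVITIES, DEFAULT_SPEED_BANDS, GridStudy

logger = logging.getLogger(__name__)

DEFAULT_MIN_DURATION = 300.0   # s; five-minute validity cut
DEFAULT_TELEPORT_LIMIT = 30.0  # m/s; max credible instantaneous speed

RULES = ("unknown_activity", "too_short", "speed_band", "teleport")


@dataclass
class CleaningRules:
    min_duration: float = DEFAULT_MIN_DURATION
    speed_bands: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPEED_BANDS))
    teleport_limit: float = DEFAULT_TELEPORT_LIMIT

    def validate(self) -> None:
        if self.min_duration <= 0 or self.teleport_limit <= 0:
            raise ValueError("cleaning rule parameters must be positive")
        for act, (lo, hi) in self.speed_bands.items():
            if not (0 <= lo < hi):
                raise ValueError(f"speed band for {act} must satisfy 0 <= lo < hi")


@dataclass
class CleaningReport:
    """Per-rule accounting of removed trajectories."""
    n_input: int
    n_retained: int
    removed_ids: Dict[str, List[str]]

    @property
    def counts(self) -> Dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed_ids.items()}

    @property
    def n_removed(self) -> int:
        return sum(self.counts.values())

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.n_removed

    def to_text(self) -> str:
        lines = [f"input trajectories: {self.n_input}",
                 f"retained: {self.n_retained}"]
        for rule in RULES:
            lines.append(f"removed[{rule}]: {len(self.removed_ids.get(rule, []))}")
        return "\n".join(lines) + "\n"


def summarize_trajectories(points: pd.DataFrame) -> pd.DataFrame:
    """Per-trajectory duration (s), length (m), mean and max segment speed.

    Timestamps must be strictly increasing within a trajectory.
    """
    pts = points.sort_values(["traj_id", "t"], kind="stable")
    g = pts.groupby("traj_id", sort=False)
    if (g["t"].apply(lambda t: bool((np.diff(t) <= 0).any()))).any():
        raise ValueError("timestamps must be strictly increasing within a trajectory")
    dx = g["x"].diff()
    dy = g["y"].diff()
    dt = g["t"].diff()
    seg_len = np.hypot(dx, dy)
    seg_speed = seg_len / dt
    tmp = pd.DataFrame({"traj_id": pts["traj_id"], "seg_len": seg_len,
                        "seg_speed": seg_speed})
    agg = tmp.groupby("traj_id", sort=False).agg(
        length=("seg_len", "sum"), max_seg_speed=("seg_speed", "max"))
    first = g.agg(activity=("activity", "first"), t0=("t", "min"), t1=("t", "max"))
    out = first.join(agg)
    out["duration"] = out["t1"] - out["t0"]
    out["mean_speed"] = np.where(out["duration"] > 0,
                                 out["length"] / out["duration"], 0.0)
    return out.drop(columns=["t0", "t1"])


def clean_trajectories(points: pd.DataFrame,
                       rules: CleaningRules | None = None
                       ) -> Tuple[pd.DataFrame, CleaningReport]:
    """Apply the three cleaning rules in order; return retained points and report.

    Rule order matters for the accounting: a record failing several rules
    is attributed to the first one that catches it.  Records with an
    activity tag outside the known three are rejected up front and logged.
    """
    rules = rules or CleaningRules()
    rules.validate()
    summ = summarize_trajectories(points)
    removed: Dict[str, List[str]] = {r: [] for r in RULES}

    known = summ["activity"].isin(ACTIVITIES)
    removed["unknown_activity"] = summ.index[~known].tolist()
    if removed["unknown_activity"]:
        logger.warning("rejected %d trajectories with unknown activity tags",
                       len(removed["unknown_activity"]))
    summ = summ[known]

    too_short = summ["duration"] < rules.min_duration
    removed["too_short"] = summ.index[too_short].tolist()
    summ = summ[~too_short]

    lo = summ["activity"].map({a: b[0] for a, b in rules.speed_bands.items()})
    hi = summ["activity"].map({a: b[1] for a, b in rules.speed_bands.items()})
    off_band = (summ["mean_speed"] < lo) | (summ["mean_speed"] > hi)
    removed["speed_band"] = summ.index[off_band].tolist()
    summ = summ[~off_band]

    teleport = summ["max_seg_speed"] > rules.teleport_limit
    removed["teleport"] = summ.index[teleport].tolist()
    summ = summ[~teleport]

    n_input = points["traj_id"].nunique()
    report = CleaningReport(n_input=n_input, n_retained=len(summ),
                            removed_ids=removed)
    assert report.reconciles()
    clean = points[points["traj_id"].isin(summ.index)].copy()
    return clean, report


def _split_segment(grid: GridStudy, p0, p1) -> List[Tuple[int, float]]:
    """Clip one segment to grid cells; return (unit_id, fraction) pieces.

    Fractions are of the segment's parameter (= time, constant velocity);
    pieces outside the grid get unit_id -1.
    """
    x0g, y0g = grid.origin
    s = grid.cell_size
    ts = [0.0, 1.0]
    for (a, b, o) in ((p0[0], p1[0], x0g), (p0[1], p1[1], y0g)):
        if a == b:
            continue
        lo, hi = sorted((a, b))
        k0 = int(np.ceil((lo - o) / s))
        k1 = int(np.floor((hi - o) / s))
        for k in range(k0, k1 + 1):
            line = o + k * s
            t = (line - a) / (b - a)
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(set(ts))
    pieces = []
    for t0, t1 in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (t0 + t1)
        xm = p0[0] + tm * (p1[0] - p0[0])
        ym = p0[1] + tm * (p1[1] - p0[1])
        unit = int(grid.locate(np.array([xm]), np.array([ym]))[0])
        pieces.append((unit, t1 - t0))
    return pieces


def activity_intensity(points: pd.DataFrame, grid: GridStudy,
                       mode: str = "apportion") -> pd.DataFrame:
    """Rasterise cleaned trajectories into per-unit activity intensity.

    ``apportion`` splits each trajectory's time across the cells it
    crosses by clipped segment length (time-weighted, since speed is
    constant within a segment); ``dominant`` assigns the whole duration to
    the cell holding the largest share (sensitivity mode).  Returns a wide
    table indexed by unit_id with one intensity column (s * km^-2) per
    activity; cells no trajectory touches hold 0.
    """
    if mode not in ("apportion", "dominant"):
        raise ValueError(f"unknown mode {mode!r}")
    area = grid.area_km2
    if area <= 0:
        raise ValueError("grid cells must have positive area")
    time_by = {act: np.zeros(grid.n_units) for act in ACTIVITIES}

    if points.empty:
        return pd.DataFrame({act: np.zeros(grid.n_units) for act in ACTIVITIES},
                            index=pd.Index(grid.unit_ids, name="unit_id"))
    pts = points.sort_values(["traj_id", "t"], kind="stable")
    arr_t = pts["t"].to_numpy()
    arr_x = pts["x"].to_numpy()
    arr_y = pts["y"].to_numpy()
    tids = pts["traj_id"].to_numpy()
    acts = pts["activity"].to_numpy()
    # group boundaries
    starts = np.flatnonzero(np.r_[True, tids[1:] != tids[:-1]])
    ends = np.r_[starts[1:], len(tids)]

    for a, b in zip(starts, ends):
        act = acts[a]
        if act not in time_by:
            continue
        acc: Dict[int, float] = {}
        cells = grid.locate(arr_x[a:b], arr_y[a:b])
        for i in range(a, b - 1):
            dt = arr_t[i + 1] - arr_t[i]
            c0, c1 = cells[i - a], cells[i - a + 1]
            if c0 == c1:
                if c0 >= 0:
                    acc[c0] = acc.get(c0, 0.0) + dt
                continue
            for unit, frac in _split_segment(grid, (arr_x[i], arr_y[i]),
                                             (arr_x[i + 1], arr_y[i + 1])):
                if unit >= 0:
                    acc[unit] = acc.get(unit, 0.0) + frac * dt
        if not acc:
            continue
        if mode == "dominant":
            unit = max(acc, key=acc.get)
            time_by[act][unit] += arr_t[b - 1] - arr_t[a]
        else:
            for unit, tsum in acc.items():
                time_by[act][unit] += tsum
    out = pd.DataFrame({act: v / area for act, v in time_by.items()},
                       index=pd.Index(grid.unit_ids, name="unit_id"))
    return out
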