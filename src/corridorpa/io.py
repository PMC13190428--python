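"""File formats: grid GeoJSON + factor CSV, trajectory CSV/GPX, weights.

GeoJSON output is canonicalised (sorted keys, fixed separators, floats
rounded to 9 decimals) so write-read-write round-trips are
byte-identical; the factor CSV uses a fixed ``%.9g`` float format for
the same reason.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .spatial import SpatialWeights
from .synthetic import GridStudy

FLOAT_FMT = "%.9g"


def _round9(obj):
    if isinstance(obj, float):
        return round(obj, 9)
    if isinstance(obj, dict):
        return {k: _round9(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round9(v) for v in obj]
    return obj


def _canonical_json(obj) -> str:
    return json.dumps(_round9(obj), sort_keys=True, separators=(",", ":"),
                      allow_nan=False) + "\n"


def write_grid(grid: GridStudy, geojson_path: str | Path,
               factors_path: str | Path) -> None:
    """Grid polygons to GeoJSON, factor table to CSV (canonical forms)."""
    features = []
    for uid in grid.unit_ids:
        x0, y0, x1, y1 = grid.cell_bounds(int(uid))
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [[[x0, y0], [x1, y0], [x1, y1],
                                          [x0, y1], [x0, y0]]]},
            "properties": {"unit_id": int(uid), "area_km2": grid.area_km2},
        })
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "cell_size": grid.cell_size, "nx": grid.nx, "ny": grid.ny,
            "origin": list(grid.origin), "crs": grid.crs,
            "dimension_of": grid.dimension_of,
        },
    }
    Path(geojson_path).write_text(_canonical_json(doc))
    df = grid.factors.copy()
    df.to_csv(factors_path, float_format=FLOAT_FMT)


def read_grid(geojson_path: str | Path, factors_path: str | Path) -> GridStudy:
    """Read and validate a grid written by :func:`write_grid`."""
    doc = json.loads(Path(geojson_path).read_text())
    props = doc.get("properties", {})
    if "crs" not in props:
        raise ValueError("grid file is missing a CRS declaration")
    seen = set()
    for feat in doc["features"]:
        uid = feat["properties"]["unit_id"]
        if uid in seen:
            raise ValueError(f"duplicate unit_id {uid}")
        seen.add(uid)
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon geometry for unit {uid}")
    factors = pd.read_csv(factors_path, index_col="unit_id")
    missing = seen - set(factors.index)
    if missing:
        raise ValueError(f"factor table missing units: {sorted(missing)[:5]}")
    grid = GridStudy(cell_size=float(props["cell_size"]),
                     nx=int(props["nx"]), ny=int(props["ny"]),
                     origin=tuple(props["origin"]),
                     factors=factors.sort_index(),
                     dimension_of=dict(props["dimension_of"]),
                     crs=props["crs"])
    return grid


def write_trajectories(points: pd.DataFrame, path: str | Path) -> None:
    points.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"traj_id", "activity", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    return df.astype({"t": float, "x": float, "y": float})


def read_gpx(path: str | Path, activity: str,
             ref_lat: float, ref_lon: float) -> pd.DataFrame:
    """Read GPX track points into the (traj_id, activity, t, x, y) schema.

    Coordinates are projected to local metres with an equirectangular
    projection around the declared reference point; timestamps become
    seconds from each track's first point.
    """
    R = 6_371_000.0
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(str(path)).getroot()
    frames = []
    for ti, trk in enumerate(root.findall(".//gpx:trk", ns)):
        rows = []
        for pt in trk.findall(".//gpx:trkpt", ns):
            lat = float(pt.get("lat"))
            lon = float(pt.get("lon"))
            tnode = pt.find("gpx:time", ns)
            if tnode is None:
                raise ValueError("GPX track point without a timestamp")
            t = pd.Timestamp(tnode.text).timestamp()
            x = R * math.radians(lon - ref_lon) * math.cos(math.radians(ref_lat))
            y = R * math.radians(lat - ref_lat)
            rows.append((t, x, y))
        if not rows:
            continue
        t0 = rows[0][0]
        frames.append(pd.DataFrame(
            {"traj_id": f"gpx{ti:04d}", "activity": activity,
             "t": [r[0] - t0 for r in rows],
             "x": [r[1] for r in rows], "y": [r[2] for r in rows]}))
    if not frames:
        raise ValueError("no tracks found in GPX file")
    return pd.concat(frames, ignore_index=True)


def write_weights(W: SpatialWeights, path: str | Path) -> None:
    """Neighbour-list text: one 'i: j:w j:w ...' line per unit."""
    lines = [f"# scheme={W.scheme} row_standardized={W.row_standardized}"]
    for i, nbrs in W.neighbor_lists().items():
        body = " ".join(f"{j}:{w:.9g}" for j, w in nbrs)
        lines.append(f"{i}: {body}")
    Path(path).write_text("\n".join(lines) + "\n")
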