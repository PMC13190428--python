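"""Synthetic corridor study generator with planted ground truth.

Real corridor studies of outdoor physical activity combine proprietary
fitness-app trajectories with regional geodata, neither of which can be
redistributed.  This module stands in for that data-generating process: it
lays a square analysis grid over a band buffering a generated "canal"
polyline, synthesises 34 spatially autocorrelated environmental factors in
five dimensions (service, living, ecology, built environment,
socioeconomic), plants known nonlinear responses — threshold effects,
pairwise interactions, a spatially varying coefficient, four spatial-type
archetypes, distance decay from the corridor — and draws GPS-like
trajectories whose rasterised intensity matches the planted latent
intensity.  Every downstream stage of the pipeline is therefore testable
against recorded truth.

Factor surfaces are built on a fine lattice (``base_resolution`` metres)
that depends only on the seed, then block-averaged to the requested cell
size, so the *same* planted truth can be re-gridded at 1 km, 2.5 km or
5 km for scale-sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

ACTIVITIES = ("hiking", "jogging", "cycling")

#: typing dimensions (enter spatial-type scores); the last two act as
#: moderators in the driver models only.
TYPING_DIMENSIONS = ("service", "living", "ecology")
ALL_DIMENSIONS = ("service", "living", "ecology", "built_env", "socioeconomic")

_DIM_PREFIX = {
    "service": "svc",
    "living": "liv",
    "ecology": "eco",
    "built_env": "blt",
    "socioeconomic": "soc",
}

#: factor counts per dimension (9/9/9/4/3 = 34) and how many of each are
#: redundant near-copies (4/4/2/1/1 = 12), so screening should retain a
#: 5/5/7/3/2 split.
DEFAULT_FACTOR_COUNTS = {
    "service": 9,
    "living": 9,
    "ecology": 9,
    "built_env": 4,
    "socioeconomic": 3,
}
DEFAULT_REDUNDANT_COUNTS = {
    "service": 4,
    "living": 4,
    "ecology": 2,
    "built_env": 1,
    "socioeconomic": 1,
}

ARCHETYPES = ("service", "living", "ecology", "mixed")


@dataclass
class CorridorConfig:
    """Study-region and truth parameters.

    Defaults describe the bundled small corridor: a 50 km canal reach with
    a 10 km buffer on each side, gridded at 1 km (1000 cells).  Smoothing
    range, archetype separation and noise were chosen once to give factor
    surfaces with clear positive spatial autocorrelation, linearly
    separable archetypes and a visible corridor-core intensity gradient.
    """

    cell_size: float = 1000.0        # grid cell side, metres
    corridor_length: float = 50_000.0  # canal reach length, metres
    buffer_width: float = 10_000.0   # band half-width either side, metres
    seed: int = 0
    factor_counts: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_COUNTS))
    redundant_counts: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REDUNDANT_COUNTS))
    smooth_range_m: float = 3000.0   # Gaussian range of factor surfaces
    base_resolution: float = 500.0   # fine lattice for re-gridding
    archetype_margin: float = 4.5    # archetype separation, score-sd units
    noise_scale: float = 0.2         # lognormal sd of latent intensity
    mixed_share_offset: float = -0.8  # rarity of the mixed archetype
    mixed_boost: float = 4.0         # intensity multiplier of mixed cells
    distance_decay_m: float = 4000.0  # e-folding of intensity off-corridor
    redundant_rho: float = 0.95      # correlation of planted copies
    traj_rate: float = 3.0           # mean trajectories per cell/activity
    contamination: float = 0.0       # fraction of defective trajectories

    def validate(self) -> None:
        if self.cell_size <= 0 or self.corridor_length <= 0 or self.buffer_width <= 0:
            raise ValueError("cell size, corridor length and buffer width must be positive")
        if self.buffer_width < self.cell_size:
            raise ValueError("buffer width must be at least one cell size")
        if self.cell_size % self.base_resolution != 0:
            raise ValueError(
                f"cell_size {self.cell_size} must be a multiple of base_resolution "
                f"{self.base_resolution} so the same truth can be re-gridded")
        if self.contamination < 0:
            raise ValueError("contamination fraction must be nonnegative")


@dataclass
class GridStudy:
    """Square analysis units covering the corridor buffer.

    Cells are half-open ``[x0, x0+s) x [y0, y0+s)`` so point-in-cell
    assignment is unambiguous; all cells of one grid share the same area.
    """

    cell_size: float
    nx: int
    ny: int
    origin: Tuple[float, float]
    factors: pd.DataFrame           # index unit_id, one column per factor
    dimension_of: Dict[str, str]    # factor name -> dimension tag
    crs: str = "local-meters"

    @property
    def n_units(self) -> int:
        return self.nx * self.ny

    @property
    def unit_ids(self) -> np.ndarray:
        return self.factors.index.to_numpy()

    @property
    def area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def rows_cols(self) -> Tuple[np.ndarray, np.ndarray]:
        ids = self.unit_ids
        return ids // self.nx, ids % self.nx

    def centroids(self) -> np.ndarray:
        r, c = self.rows_cols()
        x0, y0 = self.origin
        s = self.cell_size
        return np.column_stack([x0 + (c + 0.5) * s, y0 + (r + 0.5) * s])

    def cell_bounds(self, unit_id: int) -> Tuple[float, float, float, float]:
        r, c = unit_id // self.nx, unit_id % self.nx
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + c * s, y0 + r * s, x0 + (c + 1) * s, y0 + (r + 1) * s)

    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map points to unit ids; -1 for points outside the grid."""
        x0, y0 = self.origin
        s = self.cell_size
        c = np.floor((np.asarray(x) - x0) / s).astype(int)
        r = np.floor((np.asarray(y) - y0) / s).astype(int)
        inside = (c >= 0) & (c < self.nx) & (r >= 0) & (r < self.ny)
        out = np.where(inside, r * self.nx + c, -1)
        return out

    def factor_names_by_dimension(self) -> Dict[str, List[str]]:
        by_dim: Dict[str, List[str]] = {d: [] for d in ALL_DIMENSIONS}
        for name, dim in self.dimension_of.items():
            by_dim[dim].append(name)
        return by_dim


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generator for validation."""

    seed: int
    config: CorridorConfig
    responses: Dict[str, dict]          # activity -> effect description
    latent_intensity: pd.DataFrame      # index unit_id, one col per activity
    archetype: pd.Series                # index unit_id -> archetype name
    archetype_margin: float
    noise_scale: float
    redundant_pairs: List[Tuple[str, str]]  # (base factor, planted copy)
    corridor_distance: pd.Series        # metres from cell centroid to canal
    contaminant_labels: Dict[str, str] = field(default_factory=dict)

    def top_drivers(self, activity: str) -> List[str]:
        r = self.responses[activity]
        return [r["threshold_factor"], r["main_linear_factor"]]


# ---------------------------------------------------------------------------
# factor-engineering formulas (the per-cell measures a real study derives
# from POI / land-use layers)

def shannon_mix(proportions: Sequence[float]) -> float:
    """Land-use mix entropy H' = -sum p_i log2 p_i, in bits.

    Zero-probability categories contribute nothing; the result lies in
    [0, log2(n)].
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("proportions must be a nonempty 1-D vector")
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def kde_centrality(points: np.ndarray, eval_points: np.ndarray,
                   bandwidth: float) -> np.ndarray:
    """Planar Gaussian kernel density of facility points.

    Uses the 2-D product Gaussian with 1/(n h^2) normalisation so the
    density integrates to one over the plane; the bandwidth is in metres
    and defaults to one cell size elsewhere in the package.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ev = np.atleast_2d(np.asarray(eval_points, dtype=float))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if pts.shape[0] == 0:
        raise ValueError("at least one point is required")
    if pts.shape[1] != 2 or ev.shape[1] != 2:
        raise ValueError("points must be (n, 2) planar coordinates")
    d2 = cdist(ev, pts, "sqeuclidean")
    n = pts.shape[0]
    return np.exp(-d2 / (2.0 * bandwidth**2)).sum(axis=1) / (
        2.0 * np.pi * n * bandwidth**2)


# ---------------------------------------------------------------------------
# corridor generation

def _fine_fields(cfg: CorridorConfig, n_fields: int, rng: np.random.Generator,
                 ny_f: int, nx_f: int, sigma_cells: float) -> np.ndarray:
    """Smoothed standard-normal random fields, shape (n_fields, ny_f, nx_f)."""
    out = np.empty((n_fields, ny_f, nx_f))
    for i in range(n_fields):
        z = rng.standard_normal((ny_f, nx_f))
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        out[i] = (z - z.mean()) / z.std()
    return out


def _block_average(field: np.ndarray, r: int) -> np.ndarray:
    ny_f, nx_f = field.shape
    return field.reshape(ny_f // r, r, nx_f // r, r).mean(axis=(1, 3))


def _canal_y(x: np.ndarray, cfg: CorridorConfig) -> np.ndarray:
    """Gently meandering canal centreline through the buffer band."""
    w = cfg.buffer_width
    return w + 0.15 * w * np.sin(2.0 * np.pi * x / cfg.corridor_length)


def _response_plan(factors_by_dim: Dict[str, List[str]]) -> Dict[str, dict]:
    """Planted effect structure per activity.

    Each activity gets two linear drivers, one symmetric-saturating
    threshold driver (strongest effect, knot at the factor median), one
    multiplicative interaction pair and one factor whose coefficient drifts
    linearly along the corridor.  Factors are drawn from the non-redundant
    base set only.
    """
    svc, liv, eco = (factors_by_dim[d] for d in ("service", "living", "ecology"))
    blt, soc = factors_by_dim["built_env"], factors_by_dim["socioeconomic"]

    def pick(lst, i):
        # tolerate reduced factor counts in small test configs
        return lst[i % len(lst)]

    return {
        "hiking": dict(
            linear={pick(eco, 0): 1.0, pick(liv, 1): 0.6},
            main_linear_factor=pick(eco, 0),
            threshold_factor=pick(eco, 4), threshold_coef=2.2, saturation=1.5,
            interaction=(pick(eco, 1), pick(blt, 0)), interaction_coef=1.2,
            varying_factor=pick(svc, 0), varying_base=0.4, varying_slope=0.8,
        ),
        "jogging": dict(
            linear={pick(blt, 1): 1.0, pick(liv, 0): 0.6},
            main_linear_factor=pick(blt, 1),
            threshold_factor=pick(blt, 2), threshold_coef=2.2, saturation=1.5,
            interaction=(pick(liv, 2), pick(eco, 2)), interaction_coef=1.2,
            varying_factor=pick(liv, 3), varying_base=0.4, varying_slope=0.8,
        ),
        "cycling": dict(
            linear={pick(liv, 4): 1.0, pick(soc, 0): 0.6},
            main_linear_factor=pick(liv, 4),
            threshold_factor=pick(svc, 1), threshold_coef=2.2, saturation=1.5,
            interaction=(pick(svc, 2), pick(blt, 1)), interaction_coef=1.2,
            varying_factor=pick(eco, 3), varying_base=0.4, varying_slope=0.8,
        ),
    }


def planted_response(X: pd.DataFrame, plan: dict, x_frac: np.ndarray) -> np.ndarray:
    """Evaluate one activity's planted response on standardised factors."""
    Z = (X - X.mean()) / X.std(ddof=0)
    r = np.zeros(len(X))
    for f, b in plan["linear"].items():
        r += b * Z[f].to_numpy()
    sat = plan["saturation"]
    r += plan["threshold_coef"] * np.clip(Z[plan["threshold_factor"]].to_numpy(),
                                          -sat, sat)
    f, g = plan["interaction"]
    r += plan["interaction_coef"] * Z[f].to_numpy() * Z[g].to_numpy()
    beta = plan["varying_base"] + plan["varying_slope"] * x_frac
    r += beta * Z[plan["varying_factor"]].to_numpy()
    return r


def generate_corridor(config: CorridorConfig | None = None, *,
                      seed: int | None = None,
                      cell_size: float | None = None) -> Tuple[GridStudy, PlantedTruth]:
    """Generate the synthetic study region and its planted truth.

    Returns the gridded factor table plus a :class:`PlantedTruth` holding
    the latent per-activity intensity, archetype labels, redundant-factor
    pairs and response structure.  Identical config and seed give
    bit-identical output; changing only ``cell_size`` re-grids the same
    underlying fine-lattice truth.
    """
    cfg = CorridorConfig() if config is None else config
    if seed is not None or cell_size is not None:
        cfg = CorridorConfig(**{**cfg.__dict__,
                                **({"seed": seed} if seed is not None else {}),
                                **({"cell_size": cell_size} if cell_size is not None else {})})
        cfg.factor_counts = dict(cfg.factor_counts)
        cfg.redundant_counts = dict(cfg.redundant_counts)
    cfg.validate()

    s = cfg.cell_size
    nx = int(np.ceil(cfg.corridor_length / s))
    ny = int(np.ceil(2.0 * cfg.buffer_width / s))
    r = int(round(s / cfg.base_resolution))
    ny_f, nx_f = ny * r, nx * r
    sigma = cfg.smooth_range_m / cfg.base_resolution

    rng = np.random.default_rng(cfg.seed)

    # archetype layout first: 4 smooth score fields, argmax, with the mixed
    # field offset downward so mixed patches are small
    arch_fields = _fine_fields(cfg, len(ARCHETYPES), rng, ny_f, nx_f, sigma * 1.5)
    arch_fields[ARCHETYPES.index("mixed")] += cfg.mixed_share_offset
    arch_fine = np.argmax(arch_fields, axis=0)

    # base (non-redundant) factor fields
    base_names: List[str] = []
    dims_of_base: List[str] = []
    for dim in ALL_DIMENSIONS:
        n_base = cfg.factor_counts[dim] - cfg.redundant_counts[dim]
        if n_base <= 0:
            raise ValueError(f"dimension {dim} must keep at least one base factor")
        prefix = _DIM_PREFIX[dim]
        for i in range(n_base):
            base_names.append(f"{prefix}_{i + 1:02d}")
            dims_of_base.append(dim)
    fields = _fine_fields(cfg, len(base_names), rng, ny_f, nx_f, sigma)

    # archetype mean shifts: each typing dimension is elevated inside its
    # archetype; mixed cells are elevated on all three (slightly less, so
    # top-two scores stay within the mixed-rule threshold).  The margin is
    # spread over the dimension's factors (delta = m / sqrt(n_dim)), which
    # separates archetypes by ~m in dimension-score units while keeping
    # pairwise factor correlations well below the screening cut.
    m = cfg.archetype_margin
    n_base_of = {d: cfg.factor_counts[d] - cfg.redundant_counts[d]
                 for d in ALL_DIMENSIONS}
    shift = np.zeros((len(base_names), ny_f, nx_f))
    for j, dim in enumerate(dims_of_base):
        if dim not in TYPING_DIMENSIONS:
            continue
        delta = m / np.sqrt(n_base_of[dim])
        own = arch_fine == ARCHETYPES.index(dim)
        mixed = arch_fine == ARCHETYPES.index("mixed")
        shift[j][own] += delta
        shift[j][mixed] += 0.9 * delta
    fields = fields + shift

    # block-average to the requested resolution
    columns = {}
    for name, fld in zip(base_names, fields):
        columns[name] = _block_average(fld, r).ravel()
    arch_votes = np.stack([_block_average((arch_fine == k).astype(float), r).ravel()
                           for k in range(len(ARCHETYPES))])
    archetype = np.array(ARCHETYPES)[np.argmax(arch_votes, axis=0)]

    # redundant near-copies, correlated rho with their base column
    redundant_pairs: List[Tuple[str, str]] = []
    dimension_of: Dict[str, str] = dict(zip(base_names, dims_of_base))
    rho = cfg.redundant_rho
    for dim in ALL_DIMENSIONS:
        n_base = cfg.factor_counts[dim] - cfg.redundant_counts[dim]
        prefix = _DIM_PREFIX[dim]
        for i in range(cfg.redundant_counts[dim]):
            base = f"{prefix}_{(i % n_base) + 1:02d}"
            copy = f"{prefix}_{n_base + i + 1:02d}"
            b = columns[base]
            bz = (b - b.mean()) / b.std()
            noise = rng.standard_normal(bz.size)
            columns[copy] = rho * bz + np.sqrt(1 - rho**2) * noise
            dimension_of[copy] = dim
            redundant_pairs.append((base, copy))

    unit_ids = np.arange(nx * ny)
    factors = pd.DataFrame(columns, index=pd.Index(unit_ids, name="unit_id"))

    grid = GridStudy(cell_size=s, nx=nx, ny=ny, origin=(0.0, 0.0),
                     factors=factors, dimension_of=dimension_of)

    # planted latent intensity per activity
    cent = grid.centroids()
    x_frac = cent[:, 0] / cfg.corridor_length
    dist = np.abs(cent[:, 1] - _canal_y(cent[:, 0], cfg))
    plans = _response_plan(grid.factor_names_by_dimension())
    boost = np.where(archetype == "mixed", cfg.mixed_boost, 1.0)
    latent = {}
    for act in ACTIVITIES:
        resp = planted_response(factors, plans[act], x_frac)
        resp = np.clip(0.35 * resp, -4.0, 4.0)
        eps = rng.standard_normal(len(resp)) * cfg.noise_scale
        latent[act] = 100.0 * np.exp(resp) * np.exp(-dist / cfg.distance_decay_m) \
            * boost * np.exp(eps)
    latent_df = pd.DataFrame(latent, index=factors.index)

    truth = PlantedTruth(
        seed=cfg.seed, config=cfg, responses=plans,
        latent_intensity=latent_df,
        archetype=pd.Series(archetype, index=factors.index, name="archetype"),
        archetype_margin=m, noise_scale=cfg.noise_scale,
        redundant_pairs=redundant_pairs,
        corridor_distance=pd.Series(dist, index=factors.index, name="dist_m"),
    )
    return grid, truth


# ---------------------------------------------------------------------------
# trajectory simulation

#: activity speed bands used both by the simulator and as cleaning
#: defaults (m/s) — conventional GPS quality-control ranges.
DEFAULT_SPEED_BANDS = {
    "hiking": (0.5, 2.5),
    "jogging": (1.5, 5.5),
    "cycling": (2.5, 12.0),
}


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Billiard reflection of a free path into [lo, hi] (triangle wave)."""
    L = hi - lo
    v = np.mod(u - lo, 2.0 * L)
    return lo + np.where(v > L, 2.0 * L - v, v)


def _walk_in_cell(rng: np.random.Generator, bounds, speed: float,
                  duration: float, dt: float = 60.0) -> np.ndarray:
    """Reflecting random walk inside a cell at near-constant segment speed.

    A free correlated random walk with segment length speed*dt is folded
    into the cell by billiard reflection; folding is piecewise isometric,
    so the path length is preserved and the mean speed stays at ``speed``
    up to the chord shortening of the few folded segments.  Returns
    (n_pts, 3) rows of (t, x, y), dt apart.
    """
    x0, y0, x1, y1 = bounds
    n_seg = max(1, int(round(duration / dt)))
    headings = rng.uniform(0, 2 * np.pi) + np.cumsum(
        rng.normal(0.0, 0.6, n_seg))
    step = speed * dt
    free = np.empty((n_seg + 1, 2))
    free[0] = (rng.uniform(x0, x1), rng.uniform(y0, y1))
    free[1:, 0] = free[0, 0] + np.cumsum(step * np.cos(headings))
    free[1:, 1] = free[0, 1] + np.cumsum(step * np.sin(headings))
    pts = np.empty((n_seg + 1, 3))
    pts[:, 0] = dt * np.arange(n_seg + 1)
    pts[:, 1] = _fold(free[:, 0], x0, x1)
    pts[:, 2] = _fold(free[:, 1], y0, y1)
    return pts


def simulate_trajectories(grid: GridStudy, truth: PlantedTruth,
                          seed: int | None = None,
                          contamination: float | None = None,
                          traj_rate: float | None = None) -> pd.DataFrame:
    """Draw trajectories whose rasterised intensity matches the latent truth.

    Per cell and activity the number of trajectories is Poisson with rate
    proportional to the planted latent intensity; each clean trajectory
    stays inside its cell, lasts 10-30 minutes and moves at a speed inside
    its activity's band.  A ``contamination`` fraction (of the clean count)
    appends defective records — too short, out-of-band speed, or with one
    teleport jump — whose ids and defect types are recorded in
    ``truth.contaminant_labels``.

    Returns a long point table (traj_id, activity, t, x, y).
    """
    cfg = truth.config
    contamination = cfg.contamination if contamination is None else contamination
    traj_rate = cfg.traj_rate if traj_rate is None else traj_rate
    if contamination < 0:
        raise ValueError("contamination fraction must be nonnegative")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    frames: List[pd.DataFrame] = []
    counter = 0
    clean_ids: List[Tuple[str, int]] = []  # (activity, unit) per clean traj
    lam_all = truth.latent_intensity
    for act in ACTIVITIES:
        lam = lam_all[act].to_numpy()
        lam = traj_rate * lam / lam.mean()
        n_per_cell = rng.poisson(lam)
        lo, hi = DEFAULT_SPEED_BANDS[act]
        for unit, n in zip(grid.unit_ids, n_per_cell):
            if n == 0:
                continue
            bounds = grid.cell_bounds(int(unit))
            for _ in range(int(n)):
                speed = rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))
                duration = rng.uniform(600.0, 1800.0)
                pts = _walk_in_cell(rng, bounds, speed, duration)
                tid = f"t{counter:06d}"
                counter += 1
                frames.append(pd.DataFrame(
                    {"traj_id": tid, "activity": act,
                     "t": pts[:, 0], "x": pts[:, 1], "y": pts[:, 2]}))
                clean_ids.append((act, int(unit)))

    # planted contaminants
    labels: Dict[str, str] = {}
    n_contam = int(round(contamination * len(clean_ids)))
    defect_cycle = ("too_short", "speed_band", "teleport")
    for i in range(n_contam):
        act, unit = clean_ids[rng.integers(len(clean_ids))]
        bounds = grid.cell_bounds(unit)
        lo, hi = DEFAULT_SPEED_BANDS[act]
        defect = defect_cycle[i % 3]
        if defect == "too_short":
            pts = _walk_in_cell(rng, bounds, 0.5 * (lo + hi), duration=120.0)
        elif defect == "speed_band":
            pts = _walk_in_cell(rng, bounds, hi * 2.5, duration=900.0)
        else:
            # teleport: a long, slow but in-band walk with one jump segment
            # whose implied speed (~35 m/s) exceeds the teleport limit while
            # the added distance keeps the mean speed inside the band, so
            # only the teleport rule catches it
            pts = _walk_in_cell(rng, bounds, lo + 0.15 * (hi - lo),
                                duration=1800.0)
            k = pts.shape[0] // 2
            pts[k:, 1] = pts[k:, 1] + 2400.0
        tid = f"t{counter:06d}"
        counter += 1
        labels[tid] = defect
        frames.append(pd.DataFrame(
            {"traj_id": tid, "activity": act,
             "t": pts[:, 0], "x": pts[:, 1], "y": pts[:, 2]}))
    truth.contaminant_labels = labels

    if not frames:
        return pd.DataFrame(columns=["traj_id", "activity", "t", "x", "y"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# small planted regression designs for driver-model validation

def planted_regression(n: int, n_factors: int = 10, seed: int = 0,
                       noise: float = 0.5,
                       knot: float = 0.0) -> Tuple[pd.DataFrame, np.ndarray, dict]:
    """I.i.d. standard-normal design with a known response.

    y = 3*f0 + 2.2*clip(f1 - knot, -1.5, 1.5) + 1.5*f2*f3 + 0.3*f4 + eps.
    The two dominant drivers are f0 and f1; (f2, f3) is the planted
    interaction pair; f1 carries a saturating threshold effect centred at
    ``knot`` (its values are drawn around the knot so the centred effect
    changes sign there).
    """
    if n_factors < 5:
        raise ValueError("need at least 5 factors")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_factors))
    X[:, 1] += knot
    cols = [f"f{j}" for j in range(n_factors)]
    y = (3.0 * X[:, 0]
         + 2.2 * np.clip(X[:, 1] - knot, -1.5, 1.5)
         + 1.5 * X[:, 2] * X[:, 3]
         + 0.3 * X[:, 4]
         + noise * rng.standard_normal(n))
    truth = dict(top_drivers=["f0", "f1"], interaction=("f2", "f3"),
                 threshold_factor="f1", knot=knot, null_factors=cols[5:])
    return pd.DataFrame(X, columns=cols), y, truth
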