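"""Spatial weights, autocorrelation statistics, and (M)GWR.

Implements the spatial-heterogeneity toolkit used on the gridded
intensity surfaces: contiguity/kNN weights, global Moran's I with a
permutation null, Getis-Ord Gi* hotspot z-scores, and geographically
weighted regression with an adaptive bisquare kernel — including the
multiscale variant (MGWR) in which each covariate receives its own
bandwidth via backfitting, so globally acting and locally acting factors
can be told apart by the spatial scale of their coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .synthetic import GridStudy


@dataclass
class SpatialWeights:
    """Sparse neighbour weights; no self-neighbours."""
    matrix: sp.csr_matrix
    scheme: str                    # rook | queen | knn
    row_standardized: bool

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())

    def neighbor_lists(self) -> Dict[int, List[Tuple[int, float]]]:
        m = self.matrix.tocoo()
        out: Dict[int, List[Tuple[int, float]]] = {i: [] for i in range(self.n)}
        for i, j, w in zip(m.row, m.col, m.data):
            out[int(i)].append((int(j), float(w)))
        return out


def build_weights(grid: Optional[GridStudy] = None,
                  points: Optional[np.ndarray] = None,
                  scheme: str = "queen", k: int = 8,
                  row_standardize: bool = True) -> SpatialWeights:
    """Contiguity weights on a grid, or kNN weights on point coordinates."""
    if scheme in ("rook", "queen"):
        if grid is None:
            raise ValueError("contiguity schemes need a grid")
        nx, ny = grid.nx, grid.ny
        n = nx * ny
        if n < 2:
            raise ValueError("need at least 2 units")
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        rows, cols = [], []
        ids = np.arange(n)
        r, c = ids // nx, ids % nx
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            ok = (rr >= 0) & (rr < ny) & (cc >= 0) & (cc < nx)
            rows.append(ids[ok])
            cols.append((rr * nx + cc)[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    elif scheme == "knn":
        if points is None:
            raise ValueError("kNN needs point coordinates")
        pts = np.asarray(points, dtype=float)
        n = len(pts)
        if n < 2:
            raise ValueError("need at least 2 units")
        if k >= n:
            raise ValueError("k must be smaller than the number of units")
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)
        rows = np.repeat(np.arange(n), k)
        cols = idx[:, 1:].ravel()   # drop self (nearest)
        W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    W.setdiag(0.0)
    W.eliminate_zeros()
    empty = np.flatnonzero(np.asarray(W.sum(axis=1)).ravel() == 0)
    if empty.size:
        warnings.warn(f"{empty.size} units have no neighbours")
    if row_standardize:
        rs = np.asarray(W.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        W = sp.diags(1.0 / rs) @ W
    return SpatialWeights(matrix=W.tocsr(), scheme=scheme,
                          row_standardized=row_standardize)


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p_one_sided: float
    p_two_sided: float
    permutations: int


def morans_i(values: np.ndarray, W: SpatialWeights,
             permutations: int = 999, seed: int = 0) -> MoranResult:
    """Global Moran's I with permutation inference.

    I = (n/S0) * (z' W z) / (z' z) on mean-centred values; expectation
    under the null is -1/(n-1); the z-score and p-values come from the
    permutation distribution (one-sided in the direction of departure,
    two-sided doubled and capped at 1).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n != W.n:
        raise ValueError("values and weights disagree on n")
    if np.ptp(v) == 0:
        raise ValueError("Moran's I is undefined for constant values")
    z = v - v.mean()
    denom = float(z @ z)
    s0 = W.s0
    Wm = W.matrix

    def stat(zc: np.ndarray) -> float:
        return float(n / s0 * (zc @ (Wm @ zc)) / denom)

    I = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    sims = np.empty(permutations)
    Z = np.empty((permutations, n))
    for b in range(permutations):
        Z[b] = rng.permutation(z)
    num = np.einsum("bn,bn->b", Z, (Wm @ Z.T).T)
    sims = n / s0 * num / denom
    mu, sd = sims.mean(), sims.std(ddof=1)
    zscore = (I - mu) / sd if sd > 0 else np.inf
    if I >= mu:
        p1 = (1 + np.sum(sims >= I)) / (permutations + 1)
    else:
        p1 = (1 + np.sum(sims <= I)) / (permutations + 1)
    return MoranResult(I=I, expected=expected, z=float(zscore),
                       p_one_sided=float(p1),
                       p_two_sided=float(min(1.0, 2 * p1)),
                       permutations=permutations)


def getis_ord_gstar(values: np.ndarray, W: SpatialWeights) -> np.ndarray:
    """Getis-Ord Gi* hotspot z-scores (self-weight included).

    Uses binary inclusion of the supplied neighbour structure plus the
    focal unit itself, with the standard global mean/variance
    normalisation; positive z marks hot spots, negative z cold spots.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("Gi* is undefined for constant values")
    B = (W.matrix != 0).astype(float)
    B = B + sp.identity(n, format="csr")
    xbar = x.mean()
    S = np.sqrt((x**2).mean() - xbar**2)
    wsum = np.asarray(B.sum(axis=1)).ravel()
    w2sum = np.asarray(B.multiply(B).sum(axis=1)).ravel()
    num = B @ x - xbar * wsum
    den = S * np.sqrt((n * w2sum - wsum**2) / (n - 1))
    return num / den


# ---------------------------------------------------------------------------
# geographically weighted regression

@dataclass
class LocalCoefficients:
    beta: pd.DataFrame            # units x covariates
    se: pd.DataFrame
    tvalues: pd.DataFrame
    bandwidth: "pd.Series | int"  # per-covariate for MGWR, scalar for GWR
    aicc: float
    trace_S: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool = True
    iterations: int = 0
    rss_history: List[float] = field(default_factory=list)

    def significant(self, level: float = 1.96) -> pd.DataFrame:
        return self.tvalues.abs() >= level


def _adaptive_bisquare(dist: np.ndarray, sorted_dist: np.ndarray,
                       bw: int) -> np.ndarray:
    """Row-wise adaptive bisquare weights: zero beyond the bw-th neighbour."""
    dk = sorted_dist[:, min(bw, sorted_dist.shape[1]) - 1][:, None]
    dk = np.maximum(dk, 1e-12)
    w = np.where(dist < dk, (1.0 - (dist / dk) ** 2) ** 2, 0.0)
    return w


def _kernel_weights(dist: np.ndarray, sorted_dist: np.ndarray,
                    bw: int, kernel: str) -> np.ndarray:
    if kernel == "bisquare":
        return _adaptive_bisquare(dist, sorted_dist, bw)
    if kernel == "uniform":
        if bw >= dist.shape[1]:
            return np.ones_like(dist)
        dk = sorted_dist[:, bw - 1][:, None]
        return (dist <= dk).astype(float)
    raise ValueError(f"unknown kernel {kernel!r}")


def gwr_fit(X: pd.DataFrame, y: np.ndarray, coords: np.ndarray,
            bandwidth: int, kernel: str = "bisquare") -> LocalCoefficients:
    """Single-bandwidth GWR by local weighted least squares.

    ``X`` must include an intercept column; the bandwidth is an adaptive
    neighbour count.  With ``kernel='uniform'`` and bandwidth n the fit
    degenerates to global OLS at every location.
    """
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if bandwidth < p + 2:
        raise ValueError("bandwidth must be at least #covariates + 2")
    dist = cdist(coords, coords)
    sdist = np.sort(dist, axis=1)
    Wk = _kernel_weights(dist, sdist, bandwidth, kernel)

    beta = np.empty((n, p))
    se = np.empty((n, p))
    hat_diag = np.empty(n)
    for i in range(n):
        w = Wk[i]
        Xw = Xm * w[:, None]
        A = Xw.T @ Xm
        b = Xw.T @ yv
        try:
            Ai = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            warnings.warn("singular local design; applying ridge jitter")
            Ai = np.linalg.inv(A + 1e-8 * np.eye(p))
        C = Ai @ Xw.T           # p x n
        beta[i] = C @ yv
        hat_diag[i] = Xm[i] @ C[:, i]
        se[i] = np.sqrt(np.maximum(np.sum((C * C), axis=1), 0.0))
    fitted = np.sum(Xm * beta, axis=1)
    resid = yv - fitted
    rss = float(resid @ resid)
    trS = float(hat_diag.sum())
    dof = max(n - trS, 1e-6)
    sigma2 = rss / dof
    se = se * np.sqrt(sigma2)
    aicc = _aicc(n, rss, trS)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    cols = list(X.columns)
    idx = X.index
    return LocalCoefficients(
        beta=pd.DataFrame(beta, columns=cols, index=idx),
        se=pd.DataFrame(se, columns=cols, index=idx),
        tvalues=pd.DataFrame(tvals, columns=cols, index=idx),
        bandwidth=bandwidth, aicc=aicc, trace_S=trS,
        fitted=fitted, residuals=resid)


def _aicc(n: int, rss: float, trS: float) -> float:
    rss = max(rss, 1e-300)
    denom = n - 2.0 - trS
    if denom <= 0:
        return np.inf
    return float(n * np.log(rss / n) + n * np.log(2 * np.pi)
                 + n * (n + trS) / denom)


#: AICc margin within which models are considered equivalent; the
#: smoothest (largest-bandwidth) candidate inside the margin is chosen,
#: the usual parsimony convention for information criteria.
AICC_TIE = 2.0


def _search_bandwidth(f, lo: int, hi: int) -> Tuple[int, Dict[int, float]]:
    """Golden-section + coarse-grid AICc search with a parsimony tie-break.

    Minimises ``f`` over integers in [lo, hi]; because AICc profiles of
    near-global covariates are extremely flat, the search also evaluates a
    geometric grid and returns the *largest* bandwidth within AICC_TIE of
    the minimum rather than the raw argmin.
    """
    cache: Dict[int, float] = {}

    def fe(bw: int) -> float:
        bw = int(np.clip(bw, lo, hi))
        if bw not in cache:
            cache[bw] = f(bw)
        return cache[bw]

    golden = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = int(round(b - golden * (b - a)))
    d = int(round(a + golden * (b - a)))
    while b - a > 2:
        if fe(c) < fe(d):
            b, d = d, c
            c = int(round(b - golden * (b - a)))
        else:
            a, c = c, d
            d = int(round(a + golden * (b - a)))
    for bw in range(a, b + 1):
        fe(bw)
    if hi > lo:
        for bw in np.unique(np.geomspace(lo, hi, 12).astype(int)):
            fe(int(bw))
    best_val = min(cache.values())
    best = max(bw for bw, v in cache.items() if v <= best_val + AICC_TIE)
    return best, cache


def select_bandwidth(X: pd.DataFrame, y: np.ndarray, coords: np.ndarray,
                     bounds: Optional[Tuple[int, int]] = None,
                     kernel: str = "bisquare"
                     ) -> Tuple[int, List[Tuple[int, float]]]:
    """Adaptive-bandwidth selection by AICc over integer neighbour counts.

    Golden-section search plus a coarse grid; near-ties (within 2 AICc
    units) resolve to the larger bandwidth, so globally acting designs get
    near-global bandwidths instead of an arbitrary point on a flat
    profile.  Returns the chosen bandwidth and the evaluated trace.
    """
    n, p = X.shape
    lo = max(p + 2, 10) if bounds is None else bounds[0]
    hi = n if bounds is None else bounds[1]
    if lo > hi:
        raise ValueError("bandwidth bounds are inverted")

    def f(bw: int) -> float:
        return gwr_fit(X, y, coords, bw, kernel=kernel).aicc

    best, cache = _search_bandwidth(f, lo, hi)
    return best, sorted(cache.items())


# --- MGWR backfitting -------------------------------------------------------

def _univariate_local_fit(xj: np.ndarray, target: np.ndarray,
                          Wk: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Local single-regressor WLS: beta_i, fitted term, hat trace."""
    num = Wk @ (xj * target)
    den = Wk @ (xj * xj)
    den = np.where(np.abs(den) < 1e-12, 1e-12, den)
    beta = num / den
    term = beta * xj
    hat = (xj**2) * np.diag(Wk) / den
    return beta, term, float(hat.sum())


def _univariate_aicc(xj: np.ndarray, target: np.ndarray,
                     Wk: np.ndarray) -> float:
    beta, term, trS = _univariate_local_fit(xj, target, Wk)
    resid = target - term
    return _aicc(len(xj), float(resid @ resid), trS)


def mgwr_fit(X: pd.DataFrame, y: np.ndarray, coords: np.ndarray,
             tol: float = 1e-5, max_iter: int = 50,
             bounds: Optional[Tuple[int, int]] = None,
             kernel: str = "bisquare") -> LocalCoefficients:
    """Multiscale GWR by backfitting with per-covariate bandwidths.

    Covariates and response are z-scored internally (constant columns are
    kept as the intercept term).  The additive terms are initialised from
    a single-bandwidth GWR; each sweep forms every covariate's partial
    residual, re-selects that covariate's bandwidth by AICc, and refits
    its term.  Stops when the RMS change of the fitted terms, relative to
    the RMS of y, falls below ``tol``; the per-sweep residual sum of
    squares is recorded in ``rss_history`` (non-increasing in practice
    once the initial single-bandwidth misfit has been shed).
    """
    n, p = X.shape
    if n < 50:
        raise ValueError("MGWR needs at least 50 units")
    Xz = X.copy().astype(float)
    for c in Xz.columns:
        sd = Xz[c].std(ddof=0)
        if sd > 0:
            Xz[c] = (Xz[c] - Xz[c].mean()) / sd
        # constant columns (intercept) pass through unscaled
    yz = (np.asarray(y, float) - np.mean(y)) / np.std(y)
    Xm = Xz.to_numpy()
    dist = cdist(coords, coords)
    sdist = np.sort(dist, axis=1)
    lo = max(10, p + 2) if bounds is None else bounds[0]
    hi = n if bounds is None else bounds[1]

    # initialisation: near-global GWR (bandwidth = n), so the first sweep
    # sees partial residuals uncontaminated by locally overfit terms and
    # every covariate finds its own scale from there
    init = gwr_fit(Xz, yz, coords, hi, kernel=kernel)
    terms = init.beta.to_numpy() * Xm       # n x p additive terms
    betas = init.beta.to_numpy().copy()
    bws = np.full(p, hi, dtype=int)

    y_rms = float(np.sqrt(np.mean(yz**2)))
    rss_history: List[float] = []
    converged = False
    it = 0
    kern_cache: Dict[int, np.ndarray] = {}

    def kernel_for(bw: int) -> np.ndarray:
        if bw not in kern_cache:
            kern_cache[bw] = _kernel_weights(dist, sdist, bw, kernel)
        return kern_cache[bw]

    for it in range(1, max_iter + 1):
        old_terms = terms.copy()
        resid = yz - terms.sum(axis=1)
        for j in range(p):
            partial = resid + terms[:, j]
            xj = Xm[:, j]

            def f(bw: int) -> float:
                return _univariate_aicc(xj, partial, kernel_for(int(np.clip(bw, lo, hi))))

            bw_j, _ = _search_bandwidth(f, lo, hi)
            beta_j, term_j, _ = _univariate_local_fit(xj, partial, kernel_for(bw_j))
            terms[:, j] = term_j
            betas[:, j] = beta_j
            bws[j] = bw_j
            resid = yz - terms.sum(axis=1)
        rss_history.append(float(resid @ resid))
        soc = float(np.sqrt(np.mean((terms - old_terms)**2))) / y_rms
        if soc < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MGWR backfitting did not converge; returning best iterate")

    # pseudo-inference from the final per-term local fits
    fitted = terms.sum(axis=1)
    resid = yz - fitted
    rss = float(resid @ resid)
    trS = 0.0
    se = np.empty_like(betas)
    for j in range(p):
        Wk = kernel_for(int(bws[j]))
        xj = Xm[:, j]
        den = Wk @ (xj * xj)
        den = np.where(np.abs(den) < 1e-12, 1e-12, den)
        se[:, j] = np.sqrt(np.maximum((Wk**2) @ (xj**2), 0.0)) / np.abs(den) * np.abs(xj).mean()
        hat = (xj**2) * np.diag(Wk) / den
        trS += float(hat.sum())
    dof = max(n - trS, 1e-6)
    sigma2 = rss / dof
    se = se * np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, betas / se, 0.0)
    cols = list(X.columns)
    return LocalCoefficients(
        beta=pd.DataFrame(betas, columns=cols, index=X.index),
        se=pd.DataFrame(se, columns=cols, index=X.index),
        tvalues=pd.DataFrame(tvals, columns=cols, index=X.index),
        bandwidth=pd.Series(bws, index=cols, name="bandwidth"),
        aicc=_aicc(n, rss, trS), trace_S=trS,
        fitted=fitted, residuals=resid, converged=converged,
        iterations=it, rss_history=rss_history)


def aggregate_blocks(grid: GridStudy, tables: Dict[str, pd.DataFrame],
                     block: int = 4) -> Tuple[np.ndarray, Dict[str, pd.DataFrame]]:
    """Aggregate grid cells into block x block "county" units.

    Returns county centroid coordinates and, for every supplied per-unit
    table, its county-mean counterpart — the coarser level at which the
    multiscale regressions are run.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    r, c = grid.rows_cols()
    county = (r // block) * int(np.ceil(grid.nx / block)) + (c // block)
    cent = grid.centroids()
    cdf = pd.DataFrame(cent, columns=["x", "y"], index=grid.factors.index)
    cdf["county"] = county
    coords = cdf.groupby("county")[["x", "y"]].mean().to_numpy()
    out = {}
    for name, tab in tables.items():
        t = tab.copy()
        t["county"] = county
        out[name] = t.groupby("county").mean()
    return coords, out
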