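"""Spatial typing and advantage zoning.

Units are scored per typing dimension (weighted mean of the z-scored
retained factors of that dimension), clustered into four functional
types with weighted K-means (weights from the screening stage), and
finally relabelled by the mixed-space rule: a unit whose top-two
dimension scores are within ``theta`` (default 20%) of the top score is a
mixed space regardless of its cluster.  Activity advantage zones come
from Natural Breaks (Fisher's optimal 1-D partition) on the intensity
surfaces; a zone category combines the spatial type with the set of
advantaged activities (4 types x 7 nonempty subsets = 28 categories at
most).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synthetic import ACTIVITIES, TYPING_DIMENSIONS

MIXED = "mixed"
TYPE_SET = tuple(TYPING_DIMENSIONS) + (MIXED,)


def dimension_scores(factors: pd.DataFrame, weights: pd.Series,
                     dimension_of: Mapping[str, str],
                     dimensions: Sequence[str] = TYPING_DIMENSIONS) -> pd.DataFrame:
    """Per-unit dimension scores S_t.

    S_t is the weighted mean of the z-scored retained factors tagged with
    dimension t, with the screening weights renormalised within the
    dimension; comparable across dimensions of unequal factor counts.
    """
    cols: Dict[str, np.ndarray] = {}
    for dim in dimensions:
        members = [f for f in weights.index if dimension_of.get(f) == dim]
        if not members:
            raise ValueError(f"dimension {dim!r} has no retained factors")
        w = weights[members].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"dimension {dim!r} has zero total weight")
        w = w / w.sum()
        sub = factors[members]
        sd = sub.std(ddof=0).replace(0, 1.0)
        Z = (sub - sub.mean()) / sd
        cols[dim] = Z.to_numpy() @ w
    return pd.DataFrame(cols, index=factors.index)


@dataclass
class WeightedKMeansResult:
    labels: np.ndarray
    centroids: pd.DataFrame   # in the original (unscaled) feature space
    inertia: float


def weighted_kmeans(features: pd.DataFrame, weights: pd.Series, k: int,
                    n_init: int = 10, seed: int = 0) -> WeightedKMeansResult:
    """K-means under a weighted Euclidean metric.

    Features are scaled by sqrt(weight) before clustering, which is
    exactly K-means with squared distances weighted per feature;
    k-means++ initialisation, best of ``n_init`` restarts, deterministic
    for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError("k exceeds the number of units")
    w = weights.reindex(features.columns)
    if w.isna().any() or (w < 0).any():
        raise ValueError("weights must be nonnegative and cover every feature")
    scale = np.sqrt(w.to_numpy(dtype=float))
    Xs = features.to_numpy(dtype=float) * scale
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Xs)
    with np.errstate(divide="ignore", invalid="ignore"):
        cents = np.where(scale > 0, km.cluster_centers_ / scale, 0.0)
    # features with zero weight carry no metric information; report their
    # unweighted cluster means instead
    zero = scale == 0
    if zero.any():
        raw = features.to_numpy(dtype=float)
        for lbl in range(k):
            cents[lbl, zero] = raw[labels == lbl][:, zero].mean(axis=0)
    centroids = pd.DataFrame(cents, columns=features.columns)
    return WeightedKMeansResult(labels=labels, centroids=centroids,
                                inertia=float(km.inertia_))


@dataclass
class SpatialTypeMap:
    scores: pd.DataFrame       # unit x typing dimension
    cluster: np.ndarray
    cluster_name: Dict[int, str]
    final_type: pd.Series      # service | living | ecology | mixed
    s_max: pd.Series
    s_second: pd.Series
    theta: float
    low_signal: pd.Series      # True where S_max <= 0 (ratio rule degenerate)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["cluster"] = self.cluster
        out["type"] = self.final_type
        out["s_max"] = self.s_max
        out["s_second"] = self.s_second
        out["low_signal"] = self.low_signal
        return out


def classify_space_type(scores: pd.DataFrame,
                        cluster_labels: Optional[np.ndarray] = None,
                        theta: float = 0.2,
                        centroids: Optional[pd.DataFrame] = None) -> SpatialTypeMap:
    """Assign final spatial types from dimension scores and the mixed rule.

    Cluster labels (if given) are named by the dimension with the highest
    centroid score; the per-unit mixed rule then overrides: a unit is
    mixed when S_max - S_second < theta * S_max.  Units with S_max <= 0
    make the ratio rule degenerate; they keep the argmax dimension and are
    flagged low-signal.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    dims = list(scores.columns)
    vals = scores.to_numpy(dtype=float)
    order = np.argsort(vals, axis=1)
    s_max = vals[np.arange(len(vals)), order[:, -1]]
    s_second = vals[np.arange(len(vals)), order[:, -2]]
    argmax_dim = np.array(dims)[order[:, -1]]

    low = s_max <= 0
    mixed = (~low) & ((s_max - s_second) < theta * s_max)
    final = np.where(mixed, MIXED, argmax_dim)

    if cluster_labels is None:
        cluster_labels = np.zeros(len(scores), dtype=int)
        cluster_name = {0: "all"}
    else:
        cluster_name = {}
        for lbl in np.unique(cluster_labels):
            if centroids is not None:
                cd = centroids.loc[lbl, dims]
            else:
                cd = scores[cluster_labels == lbl].mean()
            cluster_name[int(lbl)] = str(cd.idxmax())
    return SpatialTypeMap(
        scores=scores, cluster=np.asarray(cluster_labels),
        cluster_name=cluster_name,
        final_type=pd.Series(final, index=scores.index, name="type"),
        s_max=pd.Series(s_max, index=scores.index, name="s_max"),
        s_second=pd.Series(s_second, index=scores.index, name="s_second"),
        theta=theta,
        low_signal=pd.Series(low, index=scores.index, name="low_signal"))


def jenks_breaks(values: Sequence[float], n_classes: int
                 ) -> Tuple[List[float], np.ndarray]:
    """Natural Breaks: Fisher's optimal contiguous 1-D partition.

    Minimises total within-class sum of squared deviations by dynamic
    programming over the sorted values.  Returns the class upper bounds
    (last one = max) and the class index of every input value.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a nonempty 1-D array")
    distinct = np.unique(v)
    if n_classes < 1 or n_classes > distinct.size:
        raise ValueError("n_classes must be between 1 and the number of distinct values")
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = s.size
    cs = np.concatenate([[0.0], np.cumsum(s)])
    cs2 = np.concatenate([[0.0], np.cumsum(s**2)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of s[i:j]
        m = j - i
        tot = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - tot * tot / m

    INF = np.inf
    # dp[c][j]: min cost of splitting s[:j] into c classes
    dp = np.full((n_classes + 1, n + 1), INF)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for c in range(1, n_classes + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                cost = dp[c - 1, i] + ssd(i, j)
                if cost < best:
                    best, arg = cost, i
            dp[c, j] = best
            back[c, j] = arg
    # recover class boundaries
    bounds = []
    j = n
    for c in range(n_classes, 0, -1):
        i = back[c, j]
        bounds.append((i, j))
        j = i
    bounds.reverse()
    breaks = [float(s[j - 1]) for _, j in bounds]
    labels_sorted = np.empty(n, dtype=int)
    for ci, (i, j) in enumerate(bounds):
        labels_sorted[i:j] = ci
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return breaks, labels


@dataclass
class AdvantageZoneMap:
    flags: pd.DataFrame            # unit x activity booleans
    jenks_class: pd.DataFrame      # unit x activity class index
    breaks: Dict[str, List[float]]
    category: pd.Series            # "type|H+J", "ecology|-" etc.

    def category_counts(self) -> pd.Series:
        return self.category.value_counts()


_ABBREV = {"hiking": "H", "jogging": "J", "cycling": "C"}


def advantage_zones(surfaces: pd.DataFrame, types: SpatialTypeMap,
                    n_classes: int = 2,
                    activities: Sequence[str] = ACTIVITIES) -> AdvantageZoneMap:
    """Overlay Natural-Breaks advantage flags with the spatial types.

    Per activity the surface is split into ``n_classes`` Jenks classes
    and the top class marks advantage.  The category of a unit is its
    spatial type combined with its advantaged-activity subset (only
    units with at least one advantaged activity carry a subset label, so
    at most 4 x 7 = 28 categories appear).
    """
    flags = {}
    classes = {}
    breaks: Dict[str, List[float]] = {}
    for act in activities:
        vals = surfaces[act].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"all-equal surface for {act}; no advantage flagged")
            flags[act] = np.zeros(len(vals), dtype=bool)
            classes[act] = np.zeros(len(vals), dtype=int)
            breaks[act] = [float(vals[0])]
            continue
        k = min(n_classes, np.unique(vals).size)
        brk, lab = jenks_breaks(vals, k)
        flags[act] = lab == k - 1
        classes[act] = lab
        breaks[act] = brk
    fdf = pd.DataFrame(flags, index=surfaces.index)
    cdf = pd.DataFrame(classes, index=surfaces.index)

    def _cat(row_type: str, row_flags) -> str:
        subset = [a for a in activities if row_flags[a]]
        if not subset:
            return f"{row_type}|-"
        return f"{row_type}|" + "+".join(_ABBREV.get(a, a[0].upper()) for a in subset)

    cats = [
        _cat(types.final_type.loc[u], fdf.loc[u]) for u in surfaces.index
    ]
    return AdvantageZoneMap(flags=fdf, jenks_class=cdf, breaks=breaks,
                            category=pd.Series(cats, index=surfaces.index,
                                               name="category"))
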