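"""Multicollinearity screening of candidate factors.

Highly correlated factor pairs are resolved with the help of a principal
component analysis: within each offending pair the member carrying less
of the retained principal-component structure is dropped.  The surviving
factors receive variance-contribution weights (squared loadings weighted
by component variance ratios) used later for weighted spatial clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    retained: List[str]
    excluded: Dict[str, Tuple[str, float]]   # name -> (partner kept, |r|)
    explained_variance_ratio: np.ndarray
    weights: pd.Series                       # over retained, sums to 1
    constant_dropped: List[str] = field(default_factory=list)

    def to_frame(self, dimension_of: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for f in self.retained:
            rows.append(dict(factor=f, retained=True, reason="",
                             weight=float(self.weights[f])))
        for f, (partner, r) in self.excluded.items():
            rows.append(dict(factor=f, retained=False,
                             reason=f"|r|={r:.3f} with {partner}", weight=0.0))
        for f in self.constant_dropped:
            rows.append(dict(factor=f, retained=False, reason="constant column",
                             weight=0.0))
        df = pd.DataFrame(rows)
        if dimension_of is not None:
            df.insert(1, "dimension", df["factor"].map(dimension_of))
        return df.sort_values("factor").reset_index(drop=True)


def pearson_matrix(factors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations; constant columns are rejected upstream."""
    if len(factors) < 3:
        raise ValueError("need at least 3 units for correlation analysis")
    X = factors.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        bad = factors.columns[X.std(axis=0) == 0].tolist()
        raise ValueError(f"constant columns have no defined correlation: {bad}")
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=factors.columns, columns=factors.columns)


def _pca_loadings(Z: np.ndarray, evr_cut: float) -> Tuple[np.ndarray, np.ndarray]:
    """Component loadings (factors x comps) covering evr_cut of variance."""
    pca = PCA()
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), evr_cut) + 1)
    k = min(k, len(evr))
    # loading of factor j on comp c: eigvec * sqrt(eigval)
    load = pca.components_[:k].T * np.sqrt(pca.explained_variance_[:k])
    return load, evr[:k]


def pca_screen(factors: pd.DataFrame,
               dimension_of: Mapping[str, str] | None = None,
               r_cut: float = 0.8,
               evr_cut: float = 0.85) -> ScreeningResult:
    """Drop one member of every |r| > r_cut pair, then weight the survivors.

    Exclusion is iterative on the currently retained set: the worst
    offending pair is resolved first (keep the member with the larger
    maximum absolute loading on the components covering ``evr_cut`` of
    variance), and correlations are re-examined until no pair exceeds the
    cut — so screening the retained set again is a no-op.  Ties prefer the
    factor whose dimension currently has fewer retained members, then the
    lexicographically smaller name, keeping all dimensions populated.
    """
    if not (0.0 < r_cut < 1.0):
        raise ValueError("r_cut must lie in (0, 1)")
    if len(factors) < 3:
        raise ValueError("need at least 3 units")
    constant = [c for c in factors.columns
                if factors[c].std(ddof=0) == 0]
    if constant:
        warnings.warn(f"auto-excluding constant columns: {constant}")
    work = factors.drop(columns=constant)

    excluded: Dict[str, Tuple[str, float]] = {}
    retained = list(work.columns)
    while True:
        sub = work[retained]
        corr = pearson_matrix(sub).to_numpy()
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= r_cut:
            break
        a, b = retained[i], retained[j]
        Z = (sub - sub.mean()) / sub.std(ddof=0)
        load, _ = _pca_loadings(Z.to_numpy(), evr_cut)
        la = np.max(np.abs(load[retained.index(a)]))
        lb = np.max(np.abs(load[retained.index(b)]))
        if not np.isclose(la, lb):
            drop = a if la < lb else b
        elif dimension_of is not None:
            counts = {d: 0 for d in set(dimension_of.values())}
            for f in retained:
                counts[dimension_of[f]] += 1
            ca = counts[dimension_of[a]]
            cb = counts[dimension_of[b]]
            # keep the member whose dimension is thinner
            if ca != cb:
                drop = a if ca > cb else b
            else:
                drop = max(a, b)
        else:
            drop = max(a, b)
        keep = b if drop == a else a
        excluded[drop] = (keep, float(absr[i, j]))
        retained.remove(drop)

    # variance-contribution weights on the retained set
    sub = work[retained]
    Z = ((sub - sub.mean()) / sub.std(ddof=0)).to_numpy()
    load, evr = _pca_loadings(Z, evr_cut)
    raw = (load**2 * evr[np.newaxis, :]).sum(axis=1)
    if raw.sum() <= 0:
        raise ValueError("degenerate PCA: no variance captured")
    weights = pd.Series(raw / raw.sum(), index=retained, name="weight")
    return ScreeningResult(retained=retained, excluded=excluded,
                           explained_variance_ratio=evr, weights=weights,
                           constant_dropped=constant)
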