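"""Nonlinear driver modelling of activity intensity.

A gradient-boosted regression-tree ensemble is fitted per activity; each
prediction is decomposed into additive per-factor Shapley attributions
(exact TreeSHAP on the ensemble, so baseline + sum of attributions equals
the prediction).  The attributions are converted into factor weights by a
variance-gain rule: for factor f, the gain is the best single-split
variance reduction of the target achievable by thresholding f's
attribution values,

    Var_total = (1/n) sum_i (y_i - ybar)^2
    Gain_f    = max_t [ Var_total - (|L|/n) Var(y_L) - (|R|/n) Var(y_R) ]
    omega_f   = Gain_f / sum_j Gain_j

with L = {i : phi_if < t}, R its complement, and t ranging over the
midpoints of consecutive sorted unique attribution values.  Thresholds
(zero crossings of the smoothed attribution-vs-factor curve) and pairwise
interaction strengths complete the driver profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold, cross_val_score

DEFAULT_HYPER = dict(n_estimators=300, max_depth=4, learning_rate=0.05)


@dataclass
class FittedDriverModel:
    model: xgb.XGBRegressor
    feature_names: List[str]
    cv_r2: float
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.feature_names])


@dataclass
class AttributionMatrix:
    """Additive per-unit, per-factor attributions (local accuracy holds)."""
    phi: pd.DataFrame        # units x factors
    baseline: float
    predictions: np.ndarray  # baseline + row sums of phi


@dataclass
class GainWeights:
    table: pd.DataFrame      # index factor: gain, threshold, weight, rank
    var_total: float
    degenerate: bool = False

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    def ranking(self) -> List[str]:
        return self.table.sort_values("weight", ascending=False).index.tolist()


def fit_driver_model(X: pd.DataFrame, y: np.ndarray,
                     hyper: Optional[dict] = None,
                     cv_folds: int = 5, seed: int = 0) -> FittedDriverModel:
    """Fit the boosted-tree regression with k-fold CV R^2 reporting.

    Deterministic under a fixed seed (single-threaded histogram trees).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or target")
    if cv_folds and len(X) < 10 * cv_folds:
        raise ValueError(f"need at least {10 * cv_folds} samples for {cv_folds}-fold CV")
    params = dict(DEFAULT_HYPER)
    if hyper:
        params.update(hyper)
    model = xgb.XGBRegressor(objective="reg:squarederror", random_state=seed,
                             n_jobs=1, tree_method="hist", **params)
    if cv_folds:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_r2 = float(cross_val_score(model, X, y, cv=cv, scoring="r2").mean())
    else:  # cv_folds=0 skips cross-validation (simulation studies)
        cv_r2 = float("nan")
    model.fit(X, y)
    return FittedDriverModel(model=model, feature_names=list(X.columns),
                             cv_r2=cv_r2, seed=seed)


def shap_attributions(fitted: FittedDriverModel, X: pd.DataFrame) -> AttributionMatrix:
    """Exact TreeSHAP attributions for every unit.

    Factors never used by any tree get a zero column; for each unit the
    baseline plus the attribution row sum reproduces the ensemble
    prediction.  Contributions and margins are accumulated tree by tree
    in float64 (the ensemble's own single-call outputs are float32, whose
    accumulation noise would otherwise dominate the local-accuracy
    identity).
    """
    if list(X.columns) != fitted.feature_names:
        raise ValueError("factor schema differs from the fitted model")
    booster = fitted.model.get_booster()
    dm = xgb.DMatrix(X, feature_names=fitted.feature_names)
    n_trees = booster.num_boosted_rounds()
    n, p = X.shape
    contribs = np.zeros((n, p + 1))
    margins = np.zeros(n)
    for i in range(n_trees):
        tree = booster[i:i + 1]
        contribs += tree.predict(dm, pred_contribs=True).astype(np.float64)
        margins += tree.predict(dm, output_margin=True).astype(np.float64)
    # every slice re-adds the global base offset; keep it once
    base_offset = (n_trees - 1) * _base_score(booster)
    margins -= base_offset
    bias = contribs[:, -1] - base_offset
    phi = pd.DataFrame(contribs[:, :-1], columns=fitted.feature_names,
                       index=X.index)
    return AttributionMatrix(phi=phi, baseline=float(bias.mean()),
                             predictions=margins)


def _base_score(booster: xgb.Booster) -> float:
    import json as _json

    cfg = _json.loads(booster.save_config())
    return float(cfg["learner"]["learner_model_param"]["base_score"])


def _best_split_gain(phi_f: np.ndarray, y: np.ndarray,
                     var_total: float) -> Tuple[float, float]:
    """Best single-split variance gain over midpoint thresholds of phi_f.

    Returns (gain, threshold); gain 0 and nan threshold when phi_f admits
    no split (constant).  O(n log n) via prefix sums; ties in phi stay on
    one side, matching the midpoint candidate set.
    """
    order = np.argsort(phi_f, kind="stable")
    p = phi_f[order]
    ys = y[order]
    n = len(ys)
    # admissible split positions: between distinct consecutive phi values
    distinct = np.flatnonzero(np.diff(p) > 0) + 1   # L = ys[:k]
    if distinct.size == 0:
        return 0.0, float("nan")
    cs = np.cumsum(ys)
    cs2 = np.cumsum(ys**2)
    k = distinct.astype(float)
    sumL, sumL2 = cs[distinct - 1], cs2[distinct - 1]
    sumR, sumR2 = cs[-1] - sumL, cs2[-1] - sumL2
    within = (sumL2 - sumL**2 / k) / n + (sumR2 - sumR**2 / (n - k)) / n
    gains = var_total - within
    best = int(np.argmax(gains))
    kbest = distinct[best]
    thr = 0.5 * (p[kbest - 1] + p[kbest])
    return float(max(gains[best], 0.0)), float(thr)


def gain_weights(phi: pd.DataFrame, y: np.ndarray) -> GainWeights:
    """Variance-gain factor weights from attributions (see module docstring)."""
    y = np.asarray(y, dtype=float)
    if len(phi) != len(y):
        raise ValueError("attribution matrix and target must align")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    var_total = float(np.mean((y - y.mean())**2))
    rows = {}
    for f in phi.columns:
        if var_total == 0.0:
            rows[f] = (0.0, float("nan"))
        else:
            rows[f] = _best_split_gain(phi[f].to_numpy(), y, var_total)
    table = pd.DataFrame(rows, index=["gain", "threshold"]).T
    total = table["gain"].sum()
    degenerate = total <= 0
    if degenerate:
        warnings.warn("all split gains are zero; falling back to uniform weights")
        table["weight"] = 1.0 / len(table)
    else:
        table["weight"] = table["gain"] / total
    table["rank"] = table["weight"].rank(ascending=False, method="min").astype(int)
    table.index.name = "factor"
    return GainWeights(table=table, var_total=var_total, degenerate=degenerate)


@dataclass
class ThresholdReport:
    factor: str
    crossings: List[dict]     # {"x":, "sign_left":, "sign_right":}
    saturations: List[float]  # x beyond which the smoothed effect flattens


def detect_thresholds(x: np.ndarray, phi_f: np.ndarray,
                      window: int = 31, slope_tol: float = 0.1,
                      factor: str = "") -> ThresholdReport:
    """Zero crossings and saturation points of the attribution curve.

    Sorts attributions by factor value, smooths with a centred moving
    average, and reports where the smoothed curve changes sign (the
    activation/inhibition thresholds) plus where its |slope| falls below
    ``slope_tol`` times the maximum |slope| after the last crossing.
    """
    x = np.asarray(x, dtype=float)
    phi_f = np.asarray(phi_f, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 points")
    if window > len(x):
        raise ValueError("smoothing window larger than the sample")
    order = np.argsort(x, kind="stable")
    xs, ps = x[order], phi_f[order]
    sm = pd.Series(ps).rolling(window, center=True, min_periods=1).mean().to_numpy()

    crossings: List[dict] = []
    sign = np.sign(sm)
    for i in range(len(sm) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            # linear interpolation of the crossing location
            x0, x1v = xs[i], xs[i + 1]
            y0, y1v = sm[i], sm[i + 1]
            xc = x0 if y1v == y0 else x0 - y0 * (x1v - x0) / (y1v - y0)
            crossings.append(dict(x=float(xc), sign_left=int(sign[i]),
                                  sign_right=int(sign[i + 1])))

    saturations: List[float] = []
    if crossings and len(xs) > 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.gradient(sm, xs)
        slope = np.nan_to_num(slope)
        ref = np.max(np.abs(slope))
        last = crossings[-1]["x"]
        after = xs > last
        flat = after & (np.abs(slope) < slope_tol * ref)
        if flat.any():
            saturations.append(float(xs[np.flatnonzero(flat)[0]]))
    return ThresholdReport(factor=factor, crossings=crossings,
                           saturations=saturations)


@dataclass
class InteractionResult:
    strength: pd.DataFrame          # long: factor_a, factor_b, strength
    direction: Dict[Tuple[str, str], np.ndarray]  # sign grid per pair

    def top_pair(self) -> Tuple[str, str]:
        row = self.strength.iloc[0]
        return (row["factor_a"], row["factor_b"])


def interaction_matrix(fitted: FittedDriverModel, X: pd.DataFrame,
                       pairs: Optional[Sequence[Tuple[str, str]]] = None,
                       lattice: int = 10) -> InteractionResult:
    """Pairwise SHAP interaction strengths and direction grids.

    Strength of (f, g) is the mean |interaction attribution| over units
    (off-diagonal symmetric halves summed); the direction grid is the
    sign of the mean interaction value over a ``lattice`` x ``lattice``
    quantile grid of the two factor values.
    """
    if list(X.columns) != fitted.feature_names:
        raise ValueError("factor schema differs from the fitted model")
    names = fitted.feature_names
    if pairs is not None:
        for f, g in pairs:
            if f not in names or g not in names:
                raise ValueError(f"unknown factor in pair ({f}, {g})")
    dm = xgb.DMatrix(X, feature_names=names)
    inter = fitted.model.get_booster().predict(dm, pred_interactions=True)
    inter = inter[:, :-1, :-1]  # drop bias row/col
    idx = {f: i for i, f in enumerate(names)}
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    rows = []
    direction: Dict[Tuple[str, str], np.ndarray] = {}
    for f, g in pairs:
        i, j = idx[f], idx[g]
        vals = inter[:, i, j] + inter[:, j, i]
        rows.append(dict(factor_a=f, factor_b=g,
                         strength=float(np.mean(np.abs(vals)))))
        qf = np.clip((pd.Series(X[f]).rank(pct=True).to_numpy() * lattice).astype(int),
                     0, lattice - 1)
        qg = np.clip((pd.Series(X[g]).rank(pct=True).to_numpy() * lattice).astype(int),
                     0, lattice - 1)
        grid = np.zeros((lattice, lattice))
        cnt = np.zeros((lattice, lattice))
        np.add.at(grid, (qf, qg), vals)
        np.add.at(cnt, (qf, qg), 1)
        with np.errstate(invalid="ignore"):
            grid = np.sign(np.where(cnt > 0, grid / np.maximum(cnt, 1), 0.0))
        direction[(f, g)] = grid
    strength = pd.DataFrame(rows).sort_values(
        "strength", ascending=False, kind="stable").reset_index(drop=True)
    return InteractionResult(strength=strength, direction=direction)
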