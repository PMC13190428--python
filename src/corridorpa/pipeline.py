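"""End-to-end pipeline: simulate -> clean -> intensity -> screen ->
drivers -> spatial stats -> typing/zoning -> promotion index.

Every stage derives its seed from the root seed by hashing the stage
name, so stages are independently reproducible, and two runs with the
same config produce identical artifacts.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig
from .drivers import (FittedDriverModel, GainWeights, detect_thresholds,
                      fit_driver_model, gain_weights, interaction_matrix,
                      shap_attributions)
from .promotion import PromotionTable, conversion_efficiency, promotion_index
from .screening import ScreeningResult, pca_screen
from .spatial import (aggregate_blocks, build_weights, getis_ord_gstar,
                      gwr_fit, mgwr_fit, morans_i)
from .synthetic import (ACTIVITIES, CorridorConfig, GridStudy, PlantedTruth,
                        TYPING_DIMENSIONS, generate_corridor,
                        simulate_trajectories)
from .trajectories import (CleaningReport, CleaningRules, activity_intensity,
                           clean_trajectories)
from .zoning import (AdvantageZoneMap, SpatialTypeMap, advantage_zones,
                     classify_space_type, dimension_scores, weighted_kmeans)

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineResult:
    config: RunConfig
    grid: GridStudy
    truth: PlantedTruth
    trajectories: pd.DataFrame
    clean_points: pd.DataFrame
    cleaning_report: CleaningReport
    intensity: pd.DataFrame
    screening: ScreeningResult
    models: Dict[str, FittedDriverModel]
    weights: Dict[str, GainWeights]
    thresholds: Dict[str, list]
    interactions: Dict[str, pd.DataFrame]
    moran: pd.DataFrame
    gstar: pd.DataFrame
    mgwr_bandwidths: pd.DataFrame
    types: SpatialTypeMap
    zones: AdvantageZoneMap
    promotion: Dict[str, PromotionTable]


def run_all(config: Optional[RunConfig] = None,
            outdir: Optional[str | Path] = None) -> PipelineResult:
    """Run the full analysis chain on the synthetic corridor.

    When ``outdir`` is given, every stage artifact is written there as
    CSV/GeoJSON plus a provenance copy of the config.
    """
    cfg = config or RunConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    root = cfg.seed

    # 1. simulate
    corridor_cfg = CorridorConfig(**{**cfg.corridor.__dict__,
                                     "seed": stage_seed(root, "simulate")})
    grid, truth = generate_corridor(corridor_cfg)
    points = simulate_trajectories(grid, truth,
                                   seed=stage_seed(root, "trajectories"))
    logger.info("simulated %d units, %d trajectories", grid.n_units,
                points["traj_id"].nunique())

    # 2-3. clean + rasterize
    rules = CleaningRules(min_duration=cfg.min_duration,
                          speed_bands=cfg.speed_bands,
                          teleport_limit=cfg.teleport_limit)
    clean_pts, report = clean_trajectories(points, rules)
    intensity = activity_intensity(clean_pts, grid, mode=cfg.intensity_mode)
    logger.info("cleaning removed %d of %d trajectories", report.n_removed,
                report.n_input)

    # 4. screening
    screening = pca_screen(grid.factors, grid.dimension_of,
                           r_cut=cfg.r_cut, evr_cut=cfg.evr_cut)
    retained = screening.retained
    logger.info("screening retained %d of %d factors", len(retained),
                grid.factors.shape[1])

    # 5. driver models per activity
    X = grid.factors[retained]
    hyper = dict(n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
                 learning_rate=cfg.learning_rate)
    models: Dict[str, FittedDriverModel] = {}
    gweights: Dict[str, GainWeights] = {}
    thresholds: Dict[str, list] = {}
    interactions: Dict[str, pd.DataFrame] = {}
    for act in ACTIVITIES:
        y = intensity[act].to_numpy()
        m = fit_driver_model(X, y, hyper=hyper, cv_folds=cfg.cv_folds,
                             seed=stage_seed(root, f"driver-{act}"))
        att = shap_attributions(m, X)
        gw = gain_weights(att.phi, y)
        models[act] = m
        gweights[act] = gw
        top = gw.ranking()[:5]
        reps = []
        for f in top:
            reps.append(detect_thresholds(X[f].to_numpy(),
                                          att.phi[f].to_numpy(), factor=f))
        thresholds[act] = reps
        interactions[act] = interaction_matrix(m, X).strength
        logger.info("%s: CV R^2 = %.3f, top factors %s", act, m.cv_r2, top[:3])

    # 6. spatial statistics
    W = build_weights(grid=grid, scheme=cfg.weights_scheme, k=cfg.knn_k)
    moran_rows, gstar_cols = [], {}
    for act in ACTIVITIES:
        mr = morans_i(intensity[act].to_numpy(), W,
                      permutations=cfg.permutations,
                      seed=stage_seed(root, f"moran-{act}"))
        moran_rows.append(dict(activity=act, I=mr.I, expected=mr.expected,
                               z=mr.z, p=mr.p_one_sided))
        gstar_cols[act] = getis_ord_gstar(intensity[act].to_numpy(), W)
    moran = pd.DataFrame(moran_rows).set_index("activity")
    gstar = pd.DataFrame(gstar_cols, index=intensity.index)

    # county-level multiscale regressions on the top factors
    coords, agg = aggregate_blocks(
        grid, {"X": grid.factors[retained], "y": intensity}, cfg.county_block)
    bw_rows = []
    for act in ACTIVITIES:
        top = gweights[act].ranking()[:cfg.mgwr_covariates]
        Xc = agg["X"][top].copy()
        Xc.insert(0, "intercept", 1.0)
        yc = agg["y"][act].to_numpy()
        if len(Xc) >= 50:
            fit = mgwr_fit(Xc, yc, coords)
            for cov, bw in fit.bandwidth.items():
                bw_rows.append(dict(activity=act, covariate=cov,
                                    bandwidth=int(bw), n=len(Xc),
                                    aicc=fit.aicc, converged=fit.converged))
        else:
            logger.warning("only %d counties; skipping MGWR for %s",
                           len(Xc), act)
    mgwr_bw = pd.DataFrame(bw_rows)

    # 7. typing and advantage zones
    typing_factors = [f for f in retained
                      if grid.dimension_of[f] in TYPING_DIMENSIONS]
    scores = dimension_scores(grid.factors[retained], screening.weights,
                              grid.dimension_of)
    km = weighted_kmeans(grid.factors[typing_factors],
                         screening.weights[typing_factors],
                         k=cfg.k_clusters,
                         seed=stage_seed(root, "kmeans"))
    types = classify_space_type(scores, km.labels, theta=cfg.theta)
    zones = advantage_zones(intensity, types, n_classes=cfg.jenks_classes)

    # 8. promotion index and conversion efficiency
    areas = types.final_type.value_counts() * grid.area_km2
    promos: Dict[str, PromotionTable] = {}
    for act in ACTIVITIES:
        pt = promotion_index(intensity[act], grid.factors[retained],
                             gweights[act].weights, types.final_type,
                             activity=act)
        promos[act] = conversion_efficiency(pt, areas.to_dict())

    result = PipelineResult(
        config=cfg, grid=grid, truth=truth, trajectories=points,
        clean_points=clean_pts, cleaning_report=report, intensity=intensity,
        screening=screening, models=models, weights=gweights,
        thresholds=thresholds, interactions=interactions, moran=moran,
        gstar=gstar, mgwr_bandwidths=mgwr_bw, types=types, zones=zones,
        promotion=promos)
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def write_artifacts(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    cfg.to_yaml(outdir / "config_used.yaml")
    cio.write_grid(res.grid, outdir / "grid.geojson", outdir / "factors.csv")
    cio.write_trajectories(res.trajectories, outdir / "trajectories.csv")
    cio.write_trajectories(res.clean_points, outdir / "trajectories_clean.csv")
    (outdir / "cleaning_report.txt").write_text(res.cleaning_report.to_text())
    long_int = res.intensity.reset_index().melt(
        id_vars="unit_id", var_name="activity", value_name="intensity")
    long_int.to_csv(outdir / "intensity.csv", index=False,
                    float_format="%.9g")
    res.screening.to_frame(res.grid.dimension_of).to_csv(
        outdir / "screening.csv", index=False, float_format="%.9g")
    for act in ACTIVITIES:
        res.weights[act].table.to_csv(outdir / f"importance_{act}.csv",
                                      float_format="%.9g")
        rows = []
        for rep in res.thresholds[act]:
            for c in rep.crossings:
                rows.append(dict(factor=rep.factor, breakpoint=c["x"],
                                 sign_left=c["sign_left"],
                                 sign_right=c["sign_right"]))
        pd.DataFrame(rows, columns=["factor", "breakpoint", "sign_left",
                                    "sign_right"]).to_csv(
            outdir / f"thresholds_{act}.csv", index=False, float_format="%.9g")
        res.interactions[act].to_csv(outdir / f"interactions_{act}.csv",
                                     index=False, float_format="%.9g")
    res.moran.to_csv(outdir / "moran.csv", float_format="%.9g")
    res.gstar.to_csv(outdir / "gstar.csv", float_format="%.9g")
    res.mgwr_bandwidths.to_csv(outdir / "mgwr_bandwidths.csv", index=False,
                               float_format="%.9g")
    res.types.to_frame().to_csv(outdir / "types.csv", float_format="%.9g")
    zdf = res.zones.flags.copy()
    zdf["category"] = res.zones.category
    zdf.to_csv(outdir / "zones.csv", float_format="%.9g")
    promo = pd.concat([p.table.assign(activity=a)
                       for a, p in res.promotion.items()])
    promo.to_csv(outdir / "promotion.csv", float_format="%.9g")
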