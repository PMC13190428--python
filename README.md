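# corridorpa

Grid-level analysis of how the environment along a linear corridor (a
canal reach and its buffer) promotes outdoor physical activity — hiking,
jogging and cycling — for spatial epidemiologists and urban/landscape
planners who work with GPS trajectory data and gridded environmental
factors.

The pipeline chains seven stages, each importable on its own:

1. **Trajectory processing** — quality-control cleaning (5-minute
   duration cut, activity speed bands, 30 m/s teleport limit) and
   rasterisation into per-cell activity intensity
   `I_A = Σ within-cell time / A` (s·km⁻²), i.e. cumulative activity
   time per unit area.
2. **Factor screening** — Pearson + PCA multicollinearity screening of
   34 candidate factors in five dimensions (service, living, ecology,
   built environment, socioeconomic), with variance-contribution weights
   for the survivors.
3. **Driver models** — per-activity gradient-boosted tree regressions
   with exact TreeSHAP attributions φ, converted to factor weights by
   best-single-split variance gain:
   `Gain_f = max_t [Var_tot − (|L|/n)Var(y_L) − (|R|/n)Var(y_R)]`,
   `ω_f = Gain_f / Σ_j Gain_j`, plus threshold (sign-change) detection
   and SHAP interaction ranking.
4. **Spatial statistics** — global Moran's I with permutation inference,
   Getis-Ord Gi* hotspots, and multiscale geographically weighted
   regression (MGWR, backfitting with one adaptive-bisquare bandwidth
   per covariate, AICc-selected).
5. **Spatial typing** — dimension scores (weighted means of z-scored
   factors), weighted K-means (k = 4), and the mixed-space rule: a unit
   is *mixed* when `S_max − S_second < θ·S_max` (θ = 0.2).
6. **Advantage zoning** — Natural Breaks (Fisher-optimal 1-D partition)
   per activity; zone categories = spatial type × advantaged-activity
   subset (≤ 28 categories).
7. **Promotion index** — per type `I_t = Σ_{i∈t} P_i Σ_j S_ij ω_j`
   normalised to shares, and conversion efficiency `E_t = I_t / a_t`
   (promotion share over area share; E > 1 = promotes beyond its
   footprint).

Because the data this kind of study uses (fitness-platform trajectories,
regional geodata) cannot be redistributed, the package ships a
first-class synthetic corridor generator with planted ground truth —
spatially autocorrelated factor surfaces, redundant factor copies,
threshold/interaction/spatially-varying responses, four spatial-type
archetypes, distance decay from the corridor, and labelled trajectory
contaminants — so every stage is tested by recovering what was planted.
See `docs/methods.md` for the full model description and its limits.

## Worked example

The numbered scripts under `analysis/` replay the study on the bundled
synthetic corridor (50 km reach, 10 km buffer, 1 km cells → 1000 units)
and write their tables under `results/corridor/`:

```sh
python analysis/01_simulate_corridor.py
python analysis/02_clean_and_rasterize.py
python analysis/03_screen_factors.py
python analysis/04_fit_drivers.py
python analysis/05_spatial_heterogeneity.py
python analysis/06_type_and_zone.py
python analysis/07_promotion_efficiency.py
```

Output of the run at seed 1 (abridged):

```
1000 units on a 50 x 20 grid; 9112 trajectories
retained 22 of 34 factors
per dimension: {'service': 5, 'living': 5, 'ecology': 7, 'built_env': 3, 'socioeconomic': 2}
hiking: CV R^2 = 0.703; top factors ['eco_03', 'svc_04', 'eco_06']
hiking: Moran's I = 0.582 (z = 36.7, p = 0.001)
jogging: Moran's I = 0.579 (z = 35.7, p = 0.001)
cycling: Moran's I = 0.633 (z = 37.6, p = 0.001)
type shares: {'living': 0.355, 'ecology': 0.305, 'service': 0.295, 'mixed': 0.045}
28 distinct zone categories; 174 units hold at least one advantage flag
hiking: index shares {'ecology': 0.034, 'living': 0.548, 'mixed': 0.403,
        'service': 0.015}; max conversion efficiency in 'mixed' (8.95)
```

Reading: screening dropped exactly the 12 planted redundant factors
(5/5/7/3/2 retained); all three intensity surfaces are strongly
spatially clustered (Moran's I ≈ 0.6, permutation p = 0.001); the
classifier finds the planted small mixed type (4.5% of cells), and that
type converts its footprint into activity promotion most efficiently
(E ≈ 6.6–9.0 across activities) — the qualitative pattern planted by
the generator.

The same chain is available as a CLI (`corridorpa simulate|clean|
intensity|screen|drivers|spatial|zones|index|run-all`) and as a single
call, `corridorpa.run_all(RunConfig(seed=1), outdir=...)`, which is
bit-reproducible for a fixed seed.

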