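# Methods

`corridorpa` studies how the environment adjacent to a linear corridor (a
canal reach) promotes three outdoor activities — hiking, jogging and
cycling — at the level of square grid cells. Because the data such studies
rest on (fitness-app GPS trajectories, regional POI/land-use/remote-sensing
layers) cannot be redistributed, the package pairs every analysis stage
with a synthetic corridor generator that plants known structure, so each
stage is validated by parameter recovery rather than by re-reading numbers
off a published table.

## Activity intensity

Raw trajectories are point sequences (t, x, y) in projected metres tagged
with an activity. Cleaning removes, in order: records shorter than 5
minutes; records whose mean speed lies outside the activity's plausible
band (hiking 0.5–2.5 m/s, jogging 1.5–5.5 m/s, cycling 2.5–12 m/s —
conventional GPS quality-control ranges, configurable); and records
containing any segment faster than 30 m/s (positioning jumps). A record
failing several rules is attributed to the first rule that catches it.

Cell intensity is cumulative activity time per unit area,

    I_A = (1/A) * sum over trajectories of within-cell time   [s km^-2],

which reduces to N·d/(v·A) when each of N occurrences of length d at mean
speed v stays inside one cell. Trajectories crossing cell borders are
apportioned by clipped segment time (speed is constant within a segment,
so time and length fractions coincide); a whole-trajectory-to-dominant-cell
mode exists for sensitivity checks. Summing I_A·A over cells therefore
conserves total cleaned within-grid time exactly, which the tests assert.

## Factor screening

The 34 candidate factors come in five dimensions (9 service, 9 living,
9 ecology, 4 built-environment, 3 socioeconomic). Screening removes one
member of every factor pair correlated beyond |r| = 0.8: pairs are
resolved worst-first on the currently retained set, keeping the member
with the larger maximum absolute PCA loading on the components covering
85% of variance (ties prefer the thinner dimension, then lexicographic
order), and correlations are re-examined until no pair exceeds the cut —
so screening its own output is a no-op. Survivors receive
variance-contribution weights (squared loadings weighted by explained
variance ratios, normalised to sum 1), which later weight the spatial
clustering. Both cuts (0.8, 85%) are configurable.

## Driver models and attribution-gain weights

Per activity, a gradient-boosted regression-tree ensemble (300 trees,
depth 4, learning rate 0.05, squared error, single-threaded histogram
trees for determinism) regresses intensity on the retained factors;
5-fold CV R² is reported. Attributions are exact TreeSHAP values from the
ensemble itself. Contributions and margins are accumulated tree by tree
in float64: the library's single-call outputs are float32, and their
accumulation noise (~1e-5 on typical scales) would otherwise swamp the
local-accuracy identity baseline + Σ_f φ_if = prediction, which the
per-tree accumulation satisfies to < 1e-6.

Attributions are converted to factor weights by a variance-gain rule:
for factor f, Gain_f is the largest reduction in the target's population
variance achievable by splitting the sample at a threshold on φ_·f, with
candidate thresholds at midpoints of consecutive sorted unique
attribution values (an exhaustive single-split search, O(n log n) via
prefix sums; a brute-force bipartition oracle checks it in the tests).
Weights are ω_f = Gain_f / Σ_j Gain_j, computed per activity. Because
gains scale uniformly under positive affine transforms of the target, ω
is invariant to intensity rescaling. If every gain is zero (constant
target), the weights fall back to uniform with a warning.

Threshold detection sorts a factor's attributions by factor value,
smooths with a centred moving average (default window 31), and reports
sign changes of the smoothed curve plus the first point after the last
crossing where |slope| drops below 10% of the maximum (saturation).
Interaction strength for a factor pair is the mean absolute SHAP
interaction value; the direction grid is the sign of the mean
interaction value over a 10×10 quantile lattice.

## Spatial statistics

Contiguity weights (queen by default on grids, kNN k=8 for irregular
units) feed global Moran's I with a permutation null (999 permutations
by default; z-scores from permutation moments; one- and two-sided p) and
Getis-Ord Gi* hotspot z-scores (binary neighbourhood plus self-weight).

GWR uses an adaptive bisquare kernel — weight [1−(d/d_k)²]² inside the
k-th-nearest-neighbour radius, zero outside — with local weighted least
squares, hat-matrix-trace AICc, and pseudo-t values from the local WLS
covariance with a global residual variance (no effective-parameter
correction; maps mask at |t| ≥ 1.96). Bandwidths are integers (neighbour
counts) selected by golden-section search plus a coarse geometric grid.
Because the AICc profile of a globally acting covariate is nearly flat
over the upper half of the bandwidth range, the selector returns the
*largest* bandwidth within 2 AICc units of the minimum (the usual
information-criterion convention that differences under 2 are not
meaningful); without this, the argmin lands arbitrarily mid-profile and
global/local regimes cannot be told apart reliably.

MGWR backfits one bandwidth per covariate: covariates and response are
z-scored (the intercept column passes through), terms are initialised
from a near-global GWR fit (bandwidth = n) so the first sweep sees
partial residuals uncontaminated by local overfitting, and each sweep
re-selects every covariate's bandwidth on its partial residual and
refits that term. Iteration stops when the RMS change of the fitted
terms falls below tol (1e-5) relative to the RMS of y, or at max_iter
(50, flagged if reached). The per-sweep residual sum of squares is
recorded; it is non-increasing up to the ≤1% slack the parsimony
tie-break may trade for smoothness, and the tests assert exactly that.
"County-level" fits use block aggregates of grid cells (4×4 by default)
so the coarser-scale regression stage is exercisable on the synthetic
corridor.

## Typing, zoning, promotion

Dimension scores S_t are weighted means of the z-scored retained factors
of each typing dimension (service, living, ecology; weights renormalised
within the dimension — the only reading that makes scores comparable
across dimensions of unequal size). The built-environment and
socioeconomic dimensions act as moderators in the driver models only;
a configuration switch can include them in typing. Units are clustered
with weighted K-means (features scaled by √weight, k-means++, best of 10
restarts, k = 4), clusters are named by their highest-scoring dimension,
and the per-unit mixed rule overrides: a unit is a mixed space when
S_max − S_second < θ·S_max with θ = 0.2. Units with S_max ≤ 0 make the
ratio rule degenerate; they keep the argmax dimension and are flagged
low-signal. The rule is scale-invariant per unit and the mixed share is
non-decreasing in θ.

Natural Breaks classification is Fisher's optimal contiguous partition
(dynamic programming over sorted values, exact for the within-class-SSD
objective; verified against exhaustive enumeration). Advantage zones use
two classes per activity by default (advantage = top class; a 3-class
mode supports high/mid/low grading); a unit's zone category combines its
spatial type with its advantaged-activity subset, giving at most
4 × 7 = 28 categories.

The promotion index aggregates c_i = P_i · Σ_j S_ij ω_j over the units
of each type (P = intensity, S = z-scored retained factors, ω = the
activity's attribution-gain weights), clips negative unit contributions
at zero so the normalised index I_t is a share (an unclipped mode exists
for sensitivity), and normalises per activity. Conversion efficiency is
E_t = I_t / a_t with a_t the type's area share; E_t > 1 means the type
promotes activity beyond its footprint.

## The synthetic corridor

The generator emulates the study conditions end to end. A band of
half-width 10 km around a gently meandering 50 km canal polyline is
tiled with half-open square cells (1 km by default; 2.5 km and 5 km
supported). Factor surfaces are Gaussian-smoothed white noise
(smoothing range 3 km) built on a 500 m fine lattice that depends only
on the seed and block-averaged to the requested cell size, so the same
truth can be re-gridded across scales. Twelve factors (4/4/2/1/1 per
dimension) are planted as ρ = 0.95 near-copies of base factors, so
screening should retain 22 factors split 5/5/7/3/2 and exclude exactly
one member of each planted pair.

Four spatial-type archetypes (service, living, ecology, mixed) are laid
out as smooth random patches, with the mixed patch offset to a small
minority share. Each typing dimension's factors are elevated inside the
matching archetype by margin/√n_dim (margin 4.5), which separates
archetype centroids by ~4.5 within-archetype standard deviations in
dimension-score space while keeping same-dimension factor correlations
(~0.5) safely below the screening cut; mixed cells are elevated on all
three dimensions at 90% of that, so their top two scores fall inside the
20% mixed rule.

Latent intensity per activity combines linear effects, one saturating
threshold effect (clip at ±1.5 sd, the strongest planted driver), one
multiplicative interaction pair, and one coefficient that drifts
linearly along the corridor, all passed through an exponential link,
multiplied by exp(−distance/4 km) distance decay from the canal, a ×4
intensity boost in mixed cells (so the small mixed type attains the
highest conversion efficiency, the qualitative pattern the pipeline
must reproduce), and lognormal noise (σ = 0.2).

Trajectories are drawn per cell and activity with Poisson counts
proportional to latent intensity (mean 3 per cell at the default rate),
as reflecting correlated random walks inside their cell, 10–30 min long,
at speeds inside the activity band; billiard folding keeps paths in-cell
while preserving segment lengths. A configurable contamination fraction
appends labelled defective records — 2-minute stubs, walks at 2.5× the
band ceiling, and in-band walks with a single ~35 m/s jump whose added
distance keeps the mean speed inside the band, so each defect is caught
by exactly one cleaning rule.

What the generator does *not* emulate: real road networks (network-based
accessibility measures are proxied by Euclidean constructions), GPS
measurement noise and drop-outs, map-matched routes, commuting/leisure
labels, seasonal or diurnal cycles, and any real geography. Passing
tests therefore demonstrate that the statistical machinery recovers
planted structure under realistic spatial autocorrelation and noise —
not that the substantive findings would replicate on real corridor data.

## Problem sizes and numerical choices

The bundled study runs 1000 cells, ~9000 trajectories, three boosted
models on 22 factors, 999-permutation Moran tests, and county-level MGWR
on 65 aggregated units — chosen so the full chain replays in about a
minute and a half while leaving every stage's behaviour visible.
Simulation studies in the tests use n = 300–3000 with 10–50 seeds per
claim. Degenerate inputs are handled explicitly: constant factor columns
are auto-excluded with a warning, constant targets yield uniform
fallback weights, all-equal surfaces produce no advantage flags, empty
dimensions and invalid geometries are rejected with messages. Singular
local GWR designs receive a 1e-8 ridge jitter with a warning. All
randomness flows from one root seed hashed per stage, and two runs with
the same configuration produce byte-identical artifacts.

## Known limitations

- The MGWR pseudo-t values use a simplified per-term standard error and
  no effective-parameter correction; they are meant for significance
  masking on maps, not formal inference.
- The AICc parsimony tie-break (2 units) is a convention; bandwidths for
  weakly identified covariates remain noisy near the global end.
- TreeSHAP interaction values are computed on all factor pairs in one
  pass; for very wide factor tables this is the most memory-hungry step.
- The cluster-to-type naming assumes k = 4 clusters map onto the three
  typing dimensions plus mixed; other k values work mechanically but the
  naming may merge types.
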