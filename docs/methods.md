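# Methods

## Scope and design

`antdiv` is an analysis pipeline for mapping global diversity of a
hyper-diverse, record-based taxon: occurrence QC → range estimation →
suitability modeling → richness/rarity stacking → diversity centers →
congruence and validation → a sampling-bias counterfactual → protection
coverage. Real compilations (museum/literature record databases, expert
vertebrate range maps, the global protected-area database) are not
required: a synthetic world with known ground truth supplies inputs with
the statistical structure the analysis assumes. Everything is seeded and
bit-reproducible; stage seeds derive from the master seed by a
counter-based split (`SeedSequence([master, stage_code])`), so adding a
stage never perturbs earlier streams.

All geometry stays in geographic (WGS84) coordinates. Cell areas are
analytic on the sphere — `area = R²·Δλ·(sin φ_top − sin φ_bot)`,
R = 6371 km — instead of reprojecting rasters to an equal-area CRS;
"top 10% of area" statistics accumulate these true areas directly, which
avoids resampling artifacts and is equivalent in the equal-area limit.
Metric buffering runs in a Lambert azimuthal equal-area frame centered
on each geometry, keeping buffer distances true in km without a global
projection's antimeridian edge cases. Rasters are exchanged as
plain-text ESRI ASCII grids and polygons as GeoJSON.

## Record QC

Records pool into locality groups on (normalized locality text,
normalized country, coordinates rounded to 4 decimals ≈ 11 m). Candidate
coordinates are flagged (out of ±180°/±90°, exact (0,0), missing,
country mismatch against the gazetteer); flags never raise. Resolution
is a three-rule tree: a clean original coordinate wins
(`metadata_derived`); else a geocode with consistent country and
precision radius ≤ 100 km (`geocoded`); else `unresolved` and excluded.
A record with a mismatching original but a valid geocode falls through
to rule 2 — a committed interpretation, since agreement-priority alone
does not decide the case. Metadata-derived coordinates without a stated
precision are trusted (radius 0); the 100-km rule is a property of
geocoder viewports. Records sitting within 1 km of an admin-unit
centroid *and* naming only that unit are flagged as centroids and
excluded; 1 km suffices because synthetic centroids are exact. Country
comparison is exact after case/whitespace normalization — the synthetic
gazetteer is clean, so no fuzzy matching or encoding repair is needed.

## Range estimation

Species are triaged on their count of unique occurrence localities:
fewer than 3 → union of 30-km point buffers; 3–4 → alpha hull buffered
30 km; 5 or more → suitability model inside the buffered hull. The alpha
hull keeps Delaunay triangles with circumradius ≤ α, with α = 15
interpreted in coordinate degrees (the parameter is passed to the hull
in coordinate units); degenerate point sets fall back alpha shape →
convex hull → buffered multipoint, and the fallback used is recorded.
Spatial thinning (10 km minimum nearest-neighbor distance) applies only
to the suitability-model branch and uses 20 seeded randomized greedy
passes, keeping the largest retained set; exact maximum-independent-set
search is exponential and serves only as a test oracle (the greedy
repetition strategy matches it exactly on small instances). Rasterization
uses the cell-center rule (a cell belongs to a polygon iff its center is
inside), which makes rasterized area an unbiased estimate of polygon
area.

## Suitability model

The model is a Gibbs log-linear density over the study extent:
`p(x) ∝ exp(β·f(x))`, fitted by minimizing

    L(β) = −mean_presence β·f(x) + log mean_background e^{β·f(x)}
           + Σ_f m·λ_f·|β_f|

with per-feature penalty scale `λ_f = sd_f(background)/√n_presence` —
the standard sample-size scaling, without reproducing any tool-specific
interpolation tables. Features: standardized variables (L), their
squares (Q), and forward hinges `max(0, x − k)` at 8 knots per variable
placed at equal background quantiles (H); standardization and knots are
fitted on the background only. Optimization is FISTA (proximal gradient
with backtracking), max 500 iterations, objective tolerance 1e-6; the
L1 penalty drives coefficients exactly to zero. Predictions use the
cloglog transform `1 − exp(−e^{η−r})` with `r = log mean_bg e^η`, an
entropy-equivalent normalizing offset; the transform is monotone in η.

Background is bias-matched: a Gaussian kernel density of all retained
localities (σ = 2 cells), water removed, rescaled to max 1, is used as
the sampling probability for 10,000 background draws; extents smaller
than 10,000 cells take every cell. Tuning fits {L, LQ, H, LQH} × m ∈
{1…5}; folds are leave-one-out below 25 localities, seeded random
5-fold otherwise. Evaluation metrics rank candidates on the linear
predictor (monotone in suitability but immune to cloglog saturation
when a fit separates the classes): OR10 is the mean withheld-presence
omission at the training 10-percentile threshold, AUC the Mann–Whitney
statistic of withheld presences vs background. The Continuous Boyce
Index is computed from the full-data fit (101 windows of width 1/10 of
the suitability range, Spearman of P/E against window midpoint) —
candidates are not refit for it. Selection: drop all-zero models, drop
CBI ≤ 0 or NA, minimize OR10, break ties by AUC, then by coefficient
count, then deterministically by (simpler class, smaller m). If nothing
survives the first two filters the species keeps its polygonal range
with weight 1 (the fallback the selection semantics imply but do not
state).

## Stacking, rarity, centers

Richness is the stacked weight sum; rarity dampens each species by
`1/(a_j + c)` with c = 60,000 km² (≈ a 138-km-radius circular range),
which stops single-locality "sampling islands" from dominating the map.
Continuous suitability weights enter both numerator and area: for
modeled species `a_j = Σ_i w_ij·area_i` (suitability-weighted area),
keeping the richness and rarity bookkeeping consistent — the per-species
formula leaves this open, and this is the committed choice. Centers are
detected by sorting cells by value (ties broken by cell index, so the
mask is deterministic and scale-invariant) and accumulating spherical
areas to the requested 10% of analysed area; the realized fraction
overshoots by at most one cell's share. Resolution sensitivity uses
block-maximum coarsening (a 2×2 block {0.2, 0.45, 0.9, 0.1} coarsens to
0.9; binary {0,0,1,0} to 1), NaN-ignoring, all-NaN blocks stay NaN, and
overlapping-window or non-divisible shapes are NaN-padded.

## Rarefaction surface

Windows of 60 cells at the 10-arcmin reference resolution (10°) slide at
half-window stride; the pipeline scales the window to the run's actual
resolution so the geographic span matches. Incidences are distinct
occupied cells per species (never raw record counts). Windows with fewer
than 2 occupied cells, or with as many singletons as incidences, are
omitted. The estimator is bias-corrected Chao2 with the incidence-based
coverage estimate; overlapping windows composite by per-cell averaging
(a design choice; the compositing rule is otherwise open). The estimator
targets *window* richness, so its oracle in tests is the true
species-per-window count composited the same way.

## Sampling-bias counterfactual

Predictors: environment layers, a terrain analog, the categorical realm
layer (one-hot encoded; NA cells filled by nearest labeled cell,
great-circle k = 1), companion-taxon diversity, and the sampling-density
surface. Continuous predictors are screened iteratively at |r| > 0.7
(the member of the worst pair with the larger VIF drops; density and the
categorical layer are exempt). Folds are a systematic 10 × 14
checkerboard: equal blocks, row-major block index mod 5, so horizontally
adjacent blocks never share a fold and each fold holds 28 blocks.
`mtry` (1–10) is selected by minimum average held-out MSE (ties to the
smaller value) and the forest refit on all cells; rarity responses are
log-transformed with offset = half the smallest positive value, and
predictions exponentiated back (monotone, so centers are unaffected).
The counterfactual sets the density predictor to 1 — the highest
observed density — everywhere, re-detects centers on both predictions,
and classifies cells robust / drop / enter / noncenter. Robust and drop
fractions are relative to empirical center area, enter to counterfactual
center area. Permutation importance is computed with scikit-learn's
permutation scorer on the training frame; tests assert only ranking
properties (informative predictor first, pure noise ≈ 0), which are
insensitive to the in-bag/out-of-bag distinction.

## Synthetic world

Smooth fields are sums of 12 random low-frequency cosine components
(integer frequencies ≤ 4) plus a random-magnitude latitudinal gradient —
dependency-free, seedable, smooth; fields from independent seeds are
nearly uncorrelated. The default grid is 2° over ±60° latitude
(60 × 180 = 10,800 cells, ~35% land, the southernmost 10° excluded as a
polar analog): desk-scale while preserving latitude-dependent cell
areas. Species are contiguous environmental-niche patches; the niche
threshold is bisected so realized area matches a log-normal target
(defaults: median 8×10⁵ km², log-sd 1.2, chosen so the observed
locality-count mix spans all three range-method branches the way a real
record compilation does). Collection is Poisson per occupied cell with
rate `effort × density` — purely spatial, independent of species
identity given location, matching the bias-correction assumption. The
default effort surface is a smooth field min–max rescaled to [0, 1]
(the same normalization a kernel-density effort estimate gets) raised to
1.5; effort = 5 yields a few thousand records over ~110 observed
species. Metadata noise plants missing coordinates (10%), wrong country
labels (2%), coarse geocode radii > 100 km (10%), and verbatim
duplicates (5%), each with ground-truth labels so QC precision/recall is
scored exactly. Companion taxa are Gaussian-copula rank mixes of the
*true* richness surface (they emulate independently compiled expert
maps, which the focal taxon's sampling cannot distort) at Pearson
`2·sin(π·ρ_s/6)`, the coefficient that yields Spearman ρ_s for a
bivariate normal; measured ρ is within ±0.01 of target on tie-free
references and degrades gracefully as ties (zero-richness cells) grow.
Protected areas are random overlapping rectangles added until the
covered land fraction reaches the target, with one overlapping pair
guaranteed so dissolve logic is always exercised.

What the synthetic world does **not** emulate: real taxonomy and
synonymy, temporal structure in records, coastline geometry at scale,
non-contiguous (disjunct) true ranges, and record-density magnitudes
(10³–10⁴ records rather than 10⁶). Passing tests therefore demonstrate
the correctness and calibration of the machinery under the stated
generative assumptions, not field performance on any particular real
dataset.

## The recovery experiment

The headline scientific claim the counterfactual machinery supports is
that modeling sampling density and setting it to its maximum recovers
diversity that biased collection hides. The canonical experiment
(`antdiv.pipeline.recovery_config`) makes that claim falsifiable: one
hemisphere is severely under-collected (density 0.005 vs 1.0), the pool
is 200 species with log-sd 0.8 (richness less dominated by a few
huge-range species, so true diversity is regionally balanced in
expectation), ranges are polygon-only (suitability-model noise is
orthogonal to the question), and the forest's density predictor is the
generator's *known* effort surface. The last choice matters at desk
scale: records per cell ≈ effort × occupancy, so a locality-KDE effort
estimate confounds effort with richness, and "density := 1" then
inflates well-sampled regions too — an artifact that the enormous record
volume of a real compilation suppresses but a 10³-record world does not.
The KDE estimate remains what the suitability models' background
sampling uses. Under these conditions the counterfactual map's Spearman
correlation with true diversity exceeds the empirical map's by ≈
+0.14–0.35 across seeds, against an acceptance margin of +0.05.

## Problem sizes and defaults

| Parameter | Default | Notes |
|---|---|---|
| grid | 2°, ±60° lat, 10,800 cells | analytic spherical areas |
| species | 120 (200 in recovery experiment) | log-normal range areas |
| effort | 5 records/cell at density 1 | Poisson sampling |
| buffer / alpha / thin | 30 km / 15° / 10 km | range estimation |
| background / knots / multipliers | 10,000 / 8 / 1–5 | suitability tuning |
| rarity c / center fraction | 60,000 km² / 0.10 | stacking & centers |
| collinearity / mtry / trees | 0.7 / 1–10 / 300 (pipeline), 500 (estimator default) | bias model |
| window | 60 cells @ 10′ reference (10°) | rarefaction |

The pipeline completes in ~3 minutes on one core at these sizes; the
acceptance script (pipeline + recovery experiment + spot checks) in
~6 minutes.

## Known limitations

- The alpha-hull α is in degrees, so hull concavity is anisotropic away
  from the equator; the reference analyses share this property.
- Buffering is locally equal-area but not geodesic; errors are
  negligible at 30-km buffer scales.
- The presence-background fit diverges (β → ∞ along a separating
  direction) when presences lie wholly outside the background's
  environmental support; evaluation is rank-based and unaffected, and
  the situation cannot arise in the pipeline because backgrounds are
  drawn from extents containing the presences.
- `coarsen_raster` pads edges with NaN when the factor does not divide
  the grid, slightly shrinking the effective analysed area at coarse
  resolutions.
- The counterfactual extrapolates wherever observed density never
  approaches 1 within a realm; Random Forests cannot extrapolate beyond
  training support, so "enter" cells in such regions inherit the
  best-sampled analog's diversity rather than a true prediction — the
  same caveat applies to the original protocol.
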