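# Methods

`alfrange` estimates seasonal occurrence distributions (ODs) from GPS
telemetry, derives size/shape/composition responses from them, and
tests how those responses vary with the density of anthropogenic linear
features (ALFs: paved roads, unpaved roads, fences). Because suitable
collar data are restricted, the package ships a synthetic
landscape/movement generator with known parameters; every claim the
test suite makes about the pipeline is a claim about its behavior on
those synthetic study conditions.

## Analysis unit and filters

The unit of analysis is a *fold*: one animal's fixes within one season
window of one year. Season windows are single calendar months chosen to
be safely inside residency periods — February (winter) and July
(summer) by default. A fold enters the analysis only if it has at least
20 fixes, spans at least 2 distinct calendar days, its 95% isopleth is
at least 900 m² (one 30-m raster cell), and the OD centroid lies inside
the study extent; the rules are applied in that order and the first
failure is reported. Folds are weighted by `n_points * n_days`,
normalized by the mean product within each species-season model
dataset, so the average observation carries weight 1 and the weighted
likelihood stays on a comparable scale across datasets. (Normalizing by
the max or the sum would change only the global scale of the weights,
not any relative influence.) `n_days` counts distinct calendar dates
with a fix, not elapsed time, because the one-day rule is a calendar
criterion.

## Occurrence distribution: k-LoCoH

For each fold, the convex hull of every fix and its k−1 nearest
neighbors (Euclidean distance, distance ties broken by fix index so
runs are platform-reproducible) is constructed; hulls are sorted by
area (ties again by index) and cumulatively unioned. The isopleth at
level `l` is the smallest running union covering at least a fraction
`l` of the fixes — coverage counts *points*, not hulls. Nine levels,
15% through 95% in steps of 10, are used; nesting is exact by
construction because each level's polygon extends the previous union.

Degenerate hulls (duplicate or collinear fixes, which the movement
model produces when a walker is pinned against a barrier) are kept with
area 0 and a 1e-6 m buffer so the hull count always equals the fix
count and unions stay valid.

`k` defaults to `max(3, ceil(sqrt(n)))` — the standard square-root
heuristic — and is exposed in configuration, since no single value
suits every sampling rate.

The OD is a deliberate *occurrence* (interpolative) estimator: it
describes where the animal was during the window, and its hard edges
can capture barrier effects. It is not a range-distribution estimator
and the package does not provide kernel or autocorrelated-kernel
alternatives.

### Use-intensity raster

Isopleth bands are rasterized on the 30-m template grid by cell-center
containment (boundary cells count as inside; a cell belongs to the
innermost polygon containing its center). Cells in the 15% core score
9, down to 1 in the outermost band, 0 outside; scores are normalized to
sum to 1, giving a discrete use distribution over the grid.

## Responses

* **Size** — area of the 95% isopleth; modeled as log(area in m²). The
  unit choice shifts only the intercept.
* **Shape** — the shape index `SI = P / (2*sqrt(pi*A))`, the perimeter
  relative to the circumference of the equal-area circle; 1 for a
  circle, larger for elongated or convoluted shapes. Multi-part ODs
  contribute every part, and hole rings add to the perimeter —
  LoCoH unions commonly contain holes, and an animal skirting an
  interior gap travels that boundary. SI is double-log-transformed
  (its native range is (1, ∞)), with SI clamped to 1 + 1e-6 first
  because rasterized near-circular ODs can land a hair under the
  isoperimetric bound.
* **Composition** — for each habitat attribute and ALF raster, the log
  selection ratio `logSR = log(used / available)`: `used` is the
  use-raster-weighted mean of the attribute, `available` its plain mean
  over a standardized 100-km² square centered on the fix closest to the
  OD centroid (half-open cell window, clipped at the grid edge with a
  flag). Zero handling: `available = 0` leaves the record undefined
  (the fold drops out of that attribute's models); `used = 0` — common
  for sparse binary ALF rasters — is floored at half of one cell's
  share of the domain, `delta = 1/(2 * n_cells)`, and flagged, a
  bounded imputation that preserves the avoidance ordering.

## Hypothesis models

Four weighted linear mixed models per species-season, all with a
per-animal random intercept, fold weights as above, a male indicator,
and male × ALF-availability interactions:

| | response | environmental covariates |
|---|---|---|
| H1 (size) | log area | availability of all nine attributes + nDays |
| H2 (shape) | log log SI | ALF availabilities + roughness and snow (the movement-cost attributes) + nDays |
| H3 (ALF selection, focal j ∈ ALFs) | logSR_j | avail_j + logSRs of all *other* attributes |
| H4 (habitat selection, focal j ∈ habitat) | logSR_j | avail_j + logSRs of all *other* attributes |

A response never appears among its own predictors (H3/H4), and nDays
enters only the geometry models, where tracking duration mechanically
affects OD size and shape.

Estimation is residual maximum likelihood for the random-intercept
model with fixed observation weights, `Var(e_i) = sigma^2 / w_i`. With
a single variance component the REML criterion profiles down to a
one-dimensional search over the variance ratio `lambda = tau^2 /
sigma^2`; each group's solve reduces to rank one via the Woodbury
identity, and the ratio is optimized by bounded scalar minimization on
log-lambda in [-16, 10] (xatol 1e-8). The implementation matches
`lme4::lmer(..., weights = w, REML = TRUE)` to at least five
significant figures on shared fixtures (asserted in the test suite).
When the grouping is degenerate (fewer than two animals with repeated
folds), the optimizer fails, or the variance ratio is driven to the
lower bound (a singular random intercept), the model is refit as
weighted least squares and flagged `used_random_effect = False`.
Predictors enter on their natural scale; no standardization is applied
(a configuration switch away if a user wants it). Rank-deficient
designs raise an error naming the aliased columns (detected on
unit-norm-scaled columns so predictor magnitude does not distort the
tolerance); the pipeline driver prunes aliased or all-missing terms
with a note and refits, which is what degenerate synthetic seasons
(July snow ≡ 0) require.

Prediction curves sweep one focal predictor over its observed range
with every other numeric predictor at its weighted mean and the sex
indicator at female (the reference class); intervals are
`y_hat ± 1.96 * SE(y_hat)` from the fixed-effect covariance.

## Synthetic study conditions

The generator emulates the structure of the real inputs, not their
geography:

* **Attribute rasters** — stationary Gaussian random fields on the
  30-m grid, sampled by circulant embedding so the marginal variance is
  exact at any correlation length (a correlation length beyond the grid
  gives a near-constant realization, as it should). Correlation length
  `L` is the distance at which correlation falls to exp(-1/2)
  (Gaussian covariogram). Defaults: elevation L = 900 m (mean 2000 m,
  sd 120), roughness L = 300 m (half-normal, sd 15), forage L = 400 m
  (0.45 ± 0.15, clipped to [0,1]), shrub L = 400 m (0.30 ± 0.12), tree
  L = 500 m (0.25 ± 0.15), snow L = 600 m (0.30 ± 0.10 m, February
  only; July snow is identically zero). Scales are loosely matched to
  Great Basin rangeland; only their relative spatial structure matters
  to the tests.
* **ALF networks** — per type, either random 1.5-km segments (roads)
  or a rectangular partition with filler lines (fence composites built
  from ownership boundaries look like partitions); realized length per
  unit area is trimmed to the requested density exactly. Rasterization
  is all-touched: a cell is 1 if any line touches its square, since a
  1-D line almost never covers a cell center.
* **Movement** — a discrete 2-h-step biased random walk:
  Ornstein-Uhlenbeck-style pull toward a home center (default
  attraction rate 0.15 h⁻¹, i.e. 26% of the remaining distance per
  step) plus isotropic Gaussian noise (default 250 m per-axis sd,
  an unhurried ungulate foraging scale). A proposal is accepted through
  two gates: a Metropolis habitat gate, `min(1, exp(s_new - s_old))`
  with `s = Σ beta_a z_a` on z-scored attributes, and a barrier gate —
  a proposal whose segment crosses a line of type t is rejected with
  probability 1 − permeability[t]. Up to 20 proposals per step, then
  the walker holds position; if more than half of all steps exhaust
  their retries the configuration is reported as over-constrained.

What this generator does **not** emulate, and what passing tests
therefore do not show about real data: temporal autocorrelation beyond
the OU pull, migration and dispersal, fix loss and location error,
second-order home-range placement (walkers do not choose where to live),
and any density-*dependent* behavioral avoidance of ALF cells —
barriers act only through crossing resistance. The last point matters
for interpretation: with crossing resistance alone, both the used and
the available intensity of a fence raster scale linearly with fence
density (a walker that cannot cross a wall still presses against it,
so wall cells enter its OD), and the logSR-vs-availability slope for
fences is therefore near zero in expectation rather than negative. The
recovery suite consequently demonstrates the *mean* suppression of
fence use by low permeability and the area shrinkage of enclosed
walkers; a negative density slope of the kind reported for real
ungulates additionally requires behavioral cell avoidance that this
generator deliberately does not contain.

## Numerical choices

* Isopleth coverage tolerance 1e-12 on the fraction comparison;
  use-raster mass asserted to 1e-9.
* Degenerate-hull buffer 1e-6 m; SI clamp 1e-6 above 1.
* Availability window is half-open (`[anchor−5000, anchor+5000)` per
  axis), so a 10-km window over 30-m cells holds 333 or 334 centers per
  axis depending on alignment.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single run seed; generators are bit-reproducible given (inputs, seed).
* Problem sizes in the shipped experiments: 100 recovery folds of up to
  150 fixes on 10-km tiles, 50 walkers per arm in the enclosure
  contrast, 200 point sets in the hull-oracle comparison — large enough
  for stable signs and small enough to run on a laptop in ~2 minutes.

## Known limitations

* `fold_weight` normalizes within whatever fold list it is given; the
  caller is responsible for grouping by model dataset (the pipeline
  driver does).
* The LoCoH implementation is O(n²) in fixes per fold; fine for
  telemetry folds (≤ a few thousand fixes), not for millions of points.
* Availability domains are axis-aligned squares in the projected CRS;
  no geodesic handling anywhere.
* The H3/H4 focal models assume the remaining logSR covariates are
  exogenous; no causal claims are made.
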