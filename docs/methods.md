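# Methods

This note records the statistical model, the conventions and numerical
choices behind `pathsel`, what the synthetic generators do and do not
emulate, and the known limitations.

## Telemetry cleaning

Raw fixes are hourly GPS records (animal, UTC timestamp, x/y in a projected
metric CRS, optional recorded elevation). Three screens run in a fixed
order — elevation, speed/spike, season — and are idempotent on their own
output:

* **Elevation residual.** A fix is removed iff |recorded elevation − DEM at
  the fix| > 25 m (strict). Fixes without recorded elevation pass; fixes
  outside the DEM are kept but flagged.
* **Speed and spike.** Leg speeds are distance divided by *elapsed hours*
  (gaps in the fix record are respected). One fix is removed per iteration,
  then everything is recomputed: first any fix whose incoming **and**
  outgoing legs both exceed 300 m/hr (a clearly mislocated point); then the
  worst single leg above 300 m/hr; then the worst fast-sharp-turn spike —
  an interior fix with both legs above 100 m/hr and a turn metric above
  300°. One-at-a-time removal matters: simultaneous flagging would also
  remove the innocent neighbour of a mislocated point, because both legs
  incident to it are impossible.
* **Turn metric convention.** The spike screen uses
  `(bearing_out − bearing_in) mod 360 ∈ [0°, 360°)`. This is the only
  convention under which a 300° threshold is attainable (conventional turn
  metrics are ≤180°); values just below 360° mean a slight clockwise
  continuation. The threshold and convention are configurable.
* **Season gate.** Only (animal, year) blocks with ≥1 fix in *every* month
  of the active season (April–October by default) are retained;
  "entire active season" is operationalized as month coverage because no
  stricter definition is defensible from first principles.

## Path construction

A path is a maximal run of consecutive fixes in which every adjacent pair
is 1 h apart (±5 min tolerance, absorbing logger jitter) and strictly more
than 10 m apart (the GPS error budget); runs must have ≥3 fixes and total
length strictly >100 m. A violating pair *breaks* the run — segmentation
never deletes fixes; cleaning already happened. Animals enter the analysis
with ≥6 observed paths ("more than 5"). Path turn angles are stored signed
in (−180°, 180°] for distribution fitting — deliberately a different
convention from the cleaning screen's 0–360° metric, which exists only to
apply that threshold.

## Availability: correlated random walks

Step lengths pool across *all* observed paths of all eligible animals into
a maximum-likelihood gamma fit (location fixed at 0); signed turns pool
into a wrapped-normal fit summarized by the circular mean and mean
resultant length ρ (equivalent sd = √(−2 ln ρ); ρ is clipped below 1).
Pooling at the population level avoids circularity that per-individual
fits would introduce. Each observed path gets 10 random walks sharing its
start point and step count; the first bearing is uniform (nothing else is
known about it), subsequent bearings accumulate wrapped-normal turns, and
steps are independent gamma draws. Steps leaving the raster extent are
redrawn up to a cap (20), after which the walk truncates with a warning —
a walk is never allowed to degenerate to a single point (the final fallback
clips one step inside the extent). Availability is *not* steered away from
fences or barriers: selection, not availability, is what the model
measures. Generation depends on the observed path only through its start
and step count, and is bitwise reproducible per seed.

## Covariates, encounters, gating

Each path is reduced to the unweighted mean of nearest-cell samples at
evenly spaced arc-length stations (default spacing cell/3; the even
spacing makes extraction invariant to path reversal). Nearest-cell rather
than interpolated sampling matches the 30-m raster choice, which itself
exists to absorb GPS error — sub-cell interpolation would fake precision.
Missing cells are excluded from the mean; an all-missing path yields a
missing covariate.

An animal *encounters* a feature type iff the feature polyline intersects
its home-range polygon (boundary contact counts). Home-range polygons are
inputs; when none are supplied a plain Gaussian-KDE 95% isopleth (plug-in
bandwidth) stands in, and its metadata says explicitly that it is **not**
an autocorrelated (movement-model conditioned) estimator. Animals that
never encounter a feature get that feature's covariate set missing in
every row of every one of their strata; natural covariates are never
gated.

All covariates are z-scored over the pooled observed+random rows (the
transform is stored for prediction); quadratics and interactions are
recomputed from the standardized linear columns so that `x²` is the square
of the column the coefficient multiplies. After standardization, treating
a missing value as zero equals mean imputation, and setting a column
missing for a whole stratum is *exactly* equivalent to deleting that
column from the stratum's model — the likelihood code guarantees this
identity.

## The selection model

The conditional-logistic log-likelihood is
`Σ_s [η_obs − ln Σ_m exp(η_m)]` with `η = x'β` and missing→0. The
fixed-effects fit is damped Newton with analytic gradient and Hessian,
started at β = 0, gradient tolerance 1e-8; SEs come from the inverse
observed information. Coefficients beyond |β| = 30 on z-scored covariates
signal separation: a warning is raised and the estimate is bounded.

*Poisson equivalence.* The same model re-expressed as a Poisson GLM with
one free intercept per stratum (observed row count 1, others 0) is fitted
through statsmodels as an independent route; profiling the intercepts
analytically gives the conditional likelihood minus exactly one unit per
stratum, and slope estimates agree to 1e-6.

*Random slopes.* Per-animal deviations `b_a ~ N(0, diag(σ²))` on flagged
terms are integrated out per animal by a Laplace approximation (inner
Newton to the deviation mode, log-determinant correction); the outer
optimization (L-BFGS-B) runs over fixed effects and log σ with
weakly-informative penalties — normal sd 10 on fixed effects, half-normal
scale 1 on σ — and log σ bounded in [ln 1e-3, ln 5]. A σ that lands on the
lower bound is reported with a note that the fit is effectively
fixed-effects for that term. Random slopes default to natural terms only:
gated disturbance terms are informed by few animals, too few to support a
variance component.

*WAIC.* Computed from stratum-level pointwise likelihoods under draws
(default 2000, seeded, chunked) from the normal approximation
N(β̂, V̂); `WAIC = −2(lppd − p_waic)`. A point-mass posterior gives
p_waic = 0 and −2·loglik exactly. Ranking, not the absolute WAIC value, is
the quantity of interest. The packaged 19-model ladder runs from the null
model through single-disturbance models, the disturbance backbone, natural
terms with and without quadratics, and the two interaction variants, to
the full model; ties keep input order.

## Prediction surfaces

The per-cell predictor reuses the fit-time standardization; quadratics and
interactions are rebuilt from cell values. Barrier covariates (fence,
flood control, rail by default) are held at the far log-flatten plateau
`ln 61` (standardized) — the choice of "held constant" value is ours; the
far plateau removes the barrier-following artifact, which is the stated
reason for holding them at all. Road distance is *not* held: road
avoidance is a genuine resistance signal, not a barrier artifact.
`relative_quality = exp(η − max η)` avoids overflow and has no absolute
meaning. MQI is 10 empirical quantile classes with ties assigned to the
lower class; Fisher–Jenks display classes come from the exact O(k·n²)
dynamic program, estimated on a ≤3000-cell subsample (exactness on the
sample beats a heuristic on everything) and applied to all cells. Both
classifications are invariant to affine changes of the predictor, so
rescaling or shifting β leaves the maps unchanged. Corridor patches are
connected components (8-connectivity by default) of cells at or above a
minimum class; patch minimum width is twice the maximum of the internal
Euclidean distance transform along the patch skeleton, which for an
elongated rectangle recovers the short side to cell quantization.

## The log-flatten transform

`ln(min(d, 60) + 1)` with distances from cell centers (matching
point-sampling everywhere else). The +1 m offset is a declared convention:
the log of zero distance is undefined and no offset is stated anywhere
authoritative; with it, on-feature cells score 0 and the plateau is
ln 61 ≈ 4.111. Min-then-log and log-then-cap are identical for a monotone
log. Slope comes from the Horn 3×3 estimator in degrees, with linear edge
extrapolation so edge cells get one-sided differences.

## Synthetic data: what it emulates, what it does not

`make_landscape` builds Gaussian-filtered random fields (vegetation index
≥0, habitat suitability in [0,1], wash intensity ≥0), a DEM of smooth
relief plus a mountain ridge, four typed linear features, and the
log-flattened distance rasters — deterministic per seed.

`simulate_strata` / `simulate_design` draw choice sets *exactly* from the
conditional-logistic likelihood (iid standard-normal covariates, observed
row chosen by softmax, optional per-animal coefficient deviations). These
are the generators for exact recovery, calibration and ranking tests.

`simulate_telemetry` is an agent-based stand-in for GPS loggers: at each
hourly step the agent proposes K = 20 candidate steps (gamma length capped
at 240 m so that true movement plus GPS noise on both fix ends stays under
the 300 m/hr biological speed limit; wrapped-normal turn) and accepts one
with probability ∝ exp(x'β) of the z-scored covariates at the candidate
*endpoint*; position noise (sd 8 m, under the 10 m logger error budget),
elevation noise and fix dropout (15%) follow. Cleaning violations can be
planted with a ledger of exactly which fixes should be removed. Default
coefficient signs follow the biology: against slope (with negative
quadratic), for moderate wash (negative quadratic), for vegetation and
habitat, away from roads, along fences and berms; magnitudes are ours, set
once for clear but not caricatured signal.

Because the agent selects step endpoints while the model scores path
means, the path-level fit is an approximation *at the simulation level*:
the end-to-end contract is sign and rank recovery, not unbiasedness (and
indeed barrier coefficients inflate end-to-end, because following a fence
accumulates over many steps of a path). Exact coefficient recovery is the
contract only for the likelihood-level generators. The synthetic world
also omits real-data features — burrow fidelity, behavioral states,
serially correlated GPS error, seasonal activity cycles — so passing tests
demonstrate correctness of the machinery, not field realism.

## Problem sizes used by the test suite and acceptance script

Chosen once as desk-scale defaults: likelihood oracle 200 instances;
Poisson equivalence 50 instances of ≤50 strata; recovery at 2000 strata ×
(1+10) rows; null Wald calibration 500 replicates × 200 strata;
variance-component recovery at 40 animals × 60 strata, and the
zero-variance arm 10 replicates × 20 animals × 60 strata; WAIC ladder 20
replicates × 300 strata with 1000 posterior draws; end-to-end 20
replicates of 30 agents over a two-month synthetic season
(~3400 strata/replicate; the acceptance script uses 10 such replicates).
The model-ranking experiment generates from the ladder's richest model
(full + road:wash, interaction −0.4): a generating model with a fitted
superset in the candidate set cannot be expected to rank strictly first
under WAIC, whose penalty only weakly discourages one extra noise term.

## Known limitations

* No reprojection: all layers must already share one projected metric CRS;
  mixed CRSs are refused rather than silently reprojected.
* Raster I/O is the text ESRI ASCII grid format (single band); GeoTIFF is
  not read or written.
* The Poisson-equivalence route materializes dense stratum dummies and is
  intended for verification at moderate stratum counts, not production
  fits.
* WAIC for random-slope fits draws fixed effects around the mode with
  animal deviations plugged in, understating posterior uncertainty in the
  deviations themselves.
* The KDE isopleth fallback is not a substitute for a proper home-range
  model; supply externally estimated polygons where available.
* Fisher breaks on very large surfaces are estimated on a subsample; the
  MQI (quantile) classification is always exact.
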