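# Methods

This note documents the models implemented in `escapes`, the defaults they
ship with, what the synthetic-data generator does and does not emulate, and
the numerical choices a user should know before trusting a fit.

## Rasters and geometry

All geometry is planar meters. Rasters are `(ny, nx)` arrays with a
lower-left origin, square cells, and half-open cell intervals
`[x0 + i·cs, x0 + (i+1)·cs)`, so a point on a shared boundary belongs to
exactly one cell. Persistent raster I/O uses the ESRI ASCII grid format —
a plain-text, widely supported single-band format — with nodata tagged in the
header. Inputs to a single E-scape must be pre-aligned on the same grid;
reprojection and resampling are out of scope. Habitat grids carry exactly
three classes (marsh, water, other) plus nodata; many-class cover maps are
collapsed with `aggregate_cover`, which refuses unmapped classes and
conserves cell counts.

## Resource-producing habitat layers

* **Marsh** — the marsh cover class itself.
* **Edge** (benthic microalgae) — each 4-neighbour (rook) marsh–water
  adjacency contributes one boundary segment of length `cell_size`;
  multiplying by a fixed width (default 10 m) expresses it as an area.
  Rook adjacency matches the linear-boundary semantics of edge; diagonal
  contacts share no boundary. The area is credited to the water-side cell by
  default (where benthic production is harvested); the total is identical on
  either side.
* **Phytoplankton** — water cells weighted by *relative* chlorophyll: the
  cellwise mean over the analysis window divided by the window maximum, so
  the layer is a dimensionless weight in [0, 1] and the window max is 1.

Buffer fractions use the cell-center-in-circle rule by default: at 10 m
cells against a 500 m radius the discretization error is negligible and the
rule is orders of magnitude faster than polygon clipping. An exact
cell–circle intersection rule (shapely) is available via `rule="exact"`.

## IEI and HRI

`compute_iei` draws `n_points` (default 1000, the study's protocol) random
valid cells without replacement, computes the three habitat fractions in a
500 m buffer at each, and forms `IEI_i = fsource_i / fhabitat_i`. Points
whose buffer lacks habitat *i* are dropped *for that source only* (never
assigned infinite IEI); the count is reported. Medians and IQRs summarize
the per-point values. An optional region mask restricts candidate cells;
by default all valid cells are candidates, since the source study does not
state how its random points interacted with the land–sea mask.

`compute_hri` tiles the raster into landscape foraging units (default
1 km = 100 cells) anchored at the raster origin and computes
`HRI = Σ median(IEI_i) · fhabitat_i` per unit; units with no valid cells are
nodata, and partial units at the top/right edges use the cells they contain.
`HRI = 1` is landscape-average production by construction — calibrating a
homogeneous landscape against itself returns exactly 1 everywhere, which the
test suite asserts to 1e-9. Downstream covariates use `log(HRI)`; cells with
HRI ≤ 0 yield a *missing* covariate (never −∞), and the consuming stage
decides what to do with missing values (the SSF drops the stratum and counts
it; the pipeline's HMM stage imputes log(HRI) = 0, i.e. average habitat,
with a logged count).

## Mixing model

A three-source, two-tracer concentration-dependent mixing model. For tracer
*t*, weights `w_i ∝ p_i·C_it` give the consumer-space mean
`μ_t = Σ w_i (δ_it + TEF_t)` and a predictive variance
`Σ w_i² (σ_it² + σ_TEF,t²)` plus a per-tracer residual variance. Priors:
Dirichlet(1,1,1) on the simplex (uninformative, the cited mixing package's
default in spirit) and half-Cauchy (scale 1) on the residual SDs.
Concentrations default to equal — which reduces the model to a plain
weighted mean and makes results invariant to uniform concentration
rescaling — because the source study does not print them; they are set in
`SourceSignature`, never hard-coded.

Sampling is block-wise random-walk Metropolis on additive-log-ratio
coordinates (simplex block) and log residual SDs, with per-block step-size
adaptation and, for the correlated simplex block, empirical-covariance
proposal shaping — both frozen after burn-in so the retained chain is a
valid Metropolis sampler. Defaults are a desk-scale 3 chains × 20,000
iterations (burn 10,000, thin 10); the source study's full schedule
(3 × 1,000,000, burn 500,000, thin 500) is reachable through the same
parameters. Convergence is monitored by split-R̂ per parameter (verified
against `arviz.rhat(method="split")` in the tests); any R̂ > 1.1 sets a
convergence warning on the posterior.

## Trajectory preparation

A *complete trip* runs from the last at-colony fix before the bird first
exceeds the colony radius to the first at-colony fix after re-entry, and is
kept only when both ends fall on the same calendar day. The colony radius
defaults to 500 m (not stated by the source study; configurable), and the
calendar day is evaluated in a configurable timezone (naive timestamps are
taken as local). Trips are rediscretized by piecewise-linear interpolation
in time to a 15 min lattice; recording gaps beyond `max_gap` (default
60 min) split the trip with a warning. The terminal recorded fix is always
retained, so rediscretization conserves endpoints; when the trip duration is
not a multiple of the interval this makes the final step shorter than the
rest. Turning angles are signed (counter-clockwise positive), wrapped to
(−π, π]; a zero-length step has no heading, so its turn and the next step's
turn are missing.

## Step-selection function

Movement kernels are maximum-likelihood fits: gamma on positive step lengths
(zero-length steps excluded with a count) and von Mises on defined turns.
Control steps (K = 50 per observed step, the study's ratio) are generated by
sampling a length and a turn from the kernels and rotating from the previous
heading; covariates are evaluated at the step *endpoint* (the cited
step-selection convention; the source study does not state it). Strata with
any missing covariate — case or control — are dropped whole and counted.

The estimator maximizes the exact stratified conditional (multinomial)
log-likelihood by Newton–Raphson with analytic gradient and Hessian,
internal column standardization for conditioning, and a backtracking line
search; this is identical to the partial likelihood of the Cox model with
all event times set to 1. Fixed effects are step length, log step length,
cos(turn), and log(HRI). The study's population-smooth-plus-random-smooths
construction is represented as a linear log(HRI) fixed effect with
ridge-shrunk per-individual and per-year slope deviations: the published
smooths are near-linear, and the ridge penalty plays the role of the
random-effect variance. The penalty λ is chosen by a Laplace-approximate
marginal-likelihood grid search by default, or fixed by the user. Standard
errors come from the observed information of the (penalized) likelihood; an
unconverged unpenalized fit falls back to a tiny ridge with a warning.
Relative selection strength is `exp(β · Δ log HRI)`, with per-group curves
adding the group's deviation. Deviation terms are reported with their
shrunken magnitudes; whether to pool groups is left to the user, since the
source protocol's pooling test is not fully specified.

## Covariate-transition HMM

Three behavioral states with gamma step-length emissions parameterized by
(mean, SD) — the scale states are reported on — and von Mises turn
emissions. Off-diagonal transition logits are linear in log(HRI) evaluated
at the *start* of the destination step (a modeling choice; the source study
does not state it); the diagonal is the softmax reference. Each track
starts from a uniform initial state distribution; all birds share one
likelihood (the alternative — per-bird stratification — is noted but not
implemented, as the source study does not state its pooling either).

The likelihood is the scaled forward recursion (numba-jitted core with a
pure-numpy fallback); missing turns contribute length-only emissions;
zero step lengths are rejected unless a per-state zero-inflation mass is
enabled. Fitting draws 50 restart starting values from the study's stated
uniform ranges (1–2000 m for step mean/SD, 0–2 rad for turn mean/SD; the
turn SD is converted to a concentration via κ ≈ 1/sd², with sd floored at
0.15 to keep κ finite), runs a capped L-BFGS-B pass per restart (default 30
iterations), polishes the best restart to convergence, and relabels states
in ascending mean step length so state 1/2/3 read stationary/foraging/
traveling. Tolerances: `ftol` 1e-10 per restart, final polish at the
configured tolerance (default 1e-8). The covariance of all parameters comes
from the finite-difference observed information; transition-curve CIs use
the delta method with a parametric-bootstrap fallback when the information
matrix is unusable. Viterbi decoding breaks ties toward the lower state
index.

The likelihood surface genuinely contains spurious optima (empty-state and
split-cluster solutions); in our synthetic experiments 50–90% of converged
restarts reach the dominant optimum depending on separation and data size.
The multi-restart protocol is the mitigation: the reported fit is the best
restart after polishing, and the full restart table is retained so users can
inspect consensus. Foraging segregation between colonies is the Jaccard
overlap of the 1 km cells containing foraging-decoded locations.

## Synthetic data

The generator exists to give every estimator a parameter-recovery test with
known truth; it emulates structure, not oceanography:

* **Landscapes** — thresholded smoothed Gaussian noise for marsh patches
  (patch scale controls edge density), an x-gradient plus smooth noise for
  relative chlorophyll on water cells. Real cover maps have channel
  networks, shoreline structure and class autocorrelation this does not
  reproduce.
* **Isotopes** — Gaussian scatter around the closed-form mixture mean. The
  recovery scenario draws consumers with the model-implied predictive SD at
  the true simplex (source SD and TEF SD propagated through the weights) so
  posterior intervals carry nominal coverage; real aggregate samples add
  within-school correlation the generator ignores.
* **Tracks** — days of 48 fixes at 15 min (a 12 h daylight window; the
  source study does not state tracking hours), starting at the colony with
  the first state drawn from the stationary distribution of the local
  transition matrix, states evolving by the covariate-dependent chain, and a
  forced colony return at day end so trip segmentation is exercised. Steps
  leaving the arena are re-drawn (up to 50 attempts, then redirected toward
  the colony), which truncates the step-length distribution near boundaries —
  recovery scenarios therefore use a 200 km arena of 100 m cells so boundary
  effects are negligible against ~5 km traveling steps. There is no homing,
  wind, tide or social behavior.

True state sequences are returned alongside tracks, making Viterbi accuracy
measurable (≈ 95% at the study-shaped truth).

## Benchmark problem sizes

The recovery scenarios (`escapes.scenarios`, run by
`scripts/acceptance.py`) use: 1000 IEI calibration points at 500 m radius;
200 consumer samples with 3 × 20,000 MCMC; 5000 strata with K = 50 and
β = 1 for SSF recovery plus 200 null replicates of 400 strata with K = 20;
and 30 tracks × 200 steps with 50 restarts (capped at 30 iterations each,
best polished) for the HMM. These sizes give stable estimates at desk-scale
runtimes while keeping every protocol number that defines the study design
(buffer radius, unit size, K, restart count, start ranges, MCMC shape).

## Known limitations

* Single species, three sources, two tracers; the model shapes are exactly
  study-shaped by design (parameterized, but not generalized to more
  sources/states).
* No CRS handling: coordinates must arrive in projected meters.
* The SSF represents nonlinear selection responses only through the linear
  term plus group deviations; a spline basis would slot into the same
  design-matrix hook but is not implemented.
* HMM covariance is finite-difference based; for very flat optima the
  bootstrap fallback for transition curves is the more reliable interval.
* The published field estimates depend on the deposited field data and
  external satellite rasters; this package reproduces the *methods* and
  verifies them by parameter recovery on synthetic studies.
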