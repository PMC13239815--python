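# Methods

`mpaud` implements a spatial-use analysis for Argos-tracked marine
megafauna resident at an insular foraging ground inside a marine
protected area (MPA): location-class filtering, weighted kernel
utilization distributions (UDs) with a contiguity-based bandwidth sweep,
area-based MPA containment, and a daily-step correlated-random-walk
(CRW) smoother for a migratory track. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Fix filtering and projection

Argos fixes carry a location class (LC) in {3, 2, 1, 0, A, B, Z},
ordered from most to least accurate. Two regimes are applied:

* **home_range** keeps {3, 2, 1, A}. Classes 0, B and Z have kilometre-
  scale errors that would dominate a fine-scale density estimate.
* **migration** keeps everything but Z: over a several-hundred-km
  migration more error is tolerable and directional information is worth
  keeping.

Filtering is idempotent and the home-range set is a subset of the
migration set by construction. Duplicate-time fixes (two satellite
passes) are both kept, ordered by LC accuracy then file order — the data
do not say which is "right", and the weighting downweights near-
duplicate times anyway.

The working frame is a spherical azimuthal equidistant projection
(R = 6371 km) centered on the fix centroid. At a ~30-km working extent
its distortion is far below the Argos error floor; forward/inverse
round-trip is exact to < 1e-6 degrees. A UTM-like explicit center can be
supplied through the run configuration.

## Movement model and KDE weights

Serially correlated fixes over-represent oversampled periods, and LCs
differ in accuracy, so every fix gets a two-part weight.

**Autocorrelation weight.** An isotropic Ornstein–Uhlenbeck (OU) process
(center mu, stationary per-axis variance sigma², timescale tau) is fitted
per animal by maximum likelihood using the Markov factorization
x_{i+1}|x_i ~ N(mu + φ_i(x_i − mu), sigma²(1 − φ_i²)), φ_i =
exp(−Δt_i/tau). Both mu (generalized least squares) and sigma² (closed
form) are profiled analytically, leaving a bounded one-dimensional
search over log tau (25-point log-grid, then local refinement). This is
deliberate: tracks here can have as few as a handful of usable fixes,
and the profiled 1-D likelihood is robust where a joint 4-parameter
optimization is not. Tracks with fewer than 5 fixes fall back to an IID
model (tau = 0).

Given tau, the per-fix weights are the minimum-variance weights for
estimating a mean under the OU correlation matrix
C_ij = exp(−|t_i − t_j|/tau): w ∝ C⁻¹·1, negatives clipped to zero,
renormalized to sum to one per animal. This is the closed-form
quadratic-program optimum; clustered fixes share weight, isolated fixes
carry more. Duplicate times make C singular; a 1e-8 diagonal jitter is
added and logged.

**Argos error weight.** Inverse of the mean metric error of the fix's
LC, rescaled so the most accurate class present has weight 1 (the
proportionality constant is arbitrary; the max-rescaling keeps weights
in (0, 1]). The default error table (LC 3: 490 m, 2: 1010, 1: 1200,
0: 4180, A: 6190, B: 10280; Z assigned the B value for bookkeeping) is a
literature-derived approximation from sea-turtle ground-truthing work
and is overridable via a two-column CSV.

The two weights are multiplied and the product renormalized to sum to
one per animal, so each of k pooled animals contributes total weight 1
to population-level analyses. The two normalizations (per-animal
autocorrelation sum and post-product renormalization) are this package's
choices; only the inverse-error proportionality and the multiplication
are externally fixed.

## Utilization distributions

The UD is a weighted isotropic Gaussian KDE evaluated at cell centers of
a fixed 33.7 × 19.3 km extent shared by all UDs of a run, then
renormalized to integrate to exactly 1 on the grid. The Gaussian kernel
is separable, so evaluation is two small matrix products; a brute-force
double-sum oracle is used in the tests to confirm equivalence to 1e-10.
Default cell size is 100 m (337 × 193 cells) — far below the smallest
bandwidth considered, and halving it changes a single-kernel 50% area by
well under 1%. Points outside the extent trigger a warning with the
weight fraction at risk of leaking, not an error; the extent is meant to
be conservatively large.

Isopleths are highest-density regions by cumulative-mass cell ranking:
cells sorted by density, accumulated to the target probability. This
gives exact mass accounting (enclosed mass in [p, p + max cell mass))
rather than interpolated density thresholds. Components are counted by
8-connectivity; polygons are the union of included cell squares.

**Bandwidth selection** is an ad hoc contiguity sweep: candidates
descend in 250-m steps from a start bandwidth (default: weighted
Silverman reference with Kish effective sample size, rounded up to the
next 250-m multiple) to a 250-m floor. At each candidate the 50% UD is
computed; the final bandwidth before the polygon becomes non-contiguous
is selected. A component holding under 1% of contour mass is ignored
when judging contiguity — raster contouring can emit one-cell slivers
that no analyst would call fragmentation. If no candidate fragments the
polygon, the smallest candidate producing exactly two (raw) polygons is
used as a fallback, with a flag when even that never happens. Component
counts are recorded on the way down, so the fallback needs no second
sweep.

No land-mask correction is applied: density over the island is neither
clipped nor redistributed, and containment is computed on the raw
contour.

## MPA containment

Containment is **area-based**: 100 × area(contour ∩ boundary) /
area(contour), over the union of all contour components. A mass-based
secondary statistic (UD mass integrated inside the boundary) is provided
separately (`mass_contained`) and clearly labeled — the two answer
different questions. Boundaries are read from GeoJSON, dissolved to a
single multipolygon, with invalid-ring repair attempted and logged;
Shapefile input is refused with a clear message (convert first).

## Migration: daily CRW state-space smoother

The migratory track is smoothed to one position per day with a
first-difference CRW: x_d = x_{d−1} + v_d, v_d = γ v_{d−1} + η_d,
η_d ~ N(0, σ_p² I), with γ ∈ [0, 1] the move persistence and σ_p the
process sd (m/day). An observation at fractional day t interpolates the
bracketing daily positions linearly; its error sd is the LC table value
times a single fitted inflation factor k (nominal Argos errors are
optimistic; one extra parameter keeps the model identifiable with as few
as 8 fixes). Because x_d − v_d = x_{d−1} identically, the state is just
(x, y, vx, vy) and the interpolated observation is H = [1, −(1−a)] per
axis — no augmented state needed.

(γ, σ_p, k) are estimated by maximum likelihood (Nelder–Mead on
logit γ, log σ_p, log k; best-visited point kept if the optimizer stops
early) through the Kalman prediction-error decomposition, and daily
states come from the RTS smoothing pass. Observation sd is floored at
1 m for numerical stability. Daily state count is ceil(span) + 1, with
days lacking fixes still getting states.

Travel speed is reported two ways, because "mean travel speed" from
sparse Argos data is genuinely ambiguous: (a) great-circle displacements
between consecutive smoothed daily positions (mean ± sd, n−1
denominator), and (b) raw-fix displacement over elapsed time per
segment. Both appear in the run report.

Note one subtlety confirmed by the tests: the smoothed-path
"pass-through" property (smoother interpolates noise-free daily
observations exactly) is a property of the filtering recursions at
observation noise → 0, not of the MLE — on stochastic CRW data with few
points the MLE may legitimately attribute variance to observation error.

## Residency classification

The pipeline labels an animal a migrant iff its net displacement from
the first fix exceeds a threshold (default 50 km) and the displacement
keeps increasing (non-decreasing within 5 km slack) over the final third
of fixes. An explicit migrant list in the configuration overrides the
rule. The original field decision was made by inspection; this rule is
an explicit, testable stand-in.

## Synthetic scenario

The generator emulates the study system: 9 residents whose true movement
is a stationary OU process (sd 1.5 km, tau 12 h) centered offshore of a
synthetic island inside a rectangular ~620 km² MPA, plus one migrant
leaving due south at 18 km/d with a ~1.3-day mean fix interval over
10 days. Transmitters alternate 6 h on / 6 h off; fix counts per
on-window are Poisson (mean 0.4, i.e. ~0.8 fixes/day), and per-animal
durations are uniform on 10–170 days, giving raw track sizes of roughly
ten to a couple hundred fixes. Each fix draws an LC from a B-dominated
vector (B: 0.60, A: 0.15, 0: 0.12, 1: 0.06, 2: 0.03, 3: 0.02, Z: 0.02)
and isotropic Normal error with the LC's table sd. OU sampling uses the
exact transition density, verified against the analytic lag
autocorrelation.

What the generator does **not** emulate: Argos pass geometry and the
resulting heavy-tailed, anisotropic error (a Student-t switch exists but
is off by default), habitat-driven movement (reefs, bathymetry),
tag-failure processes, and tide/diel behavior beyond the duty cycle.
Passing tests therefore demonstrate correctness of the estimators under
the stated models, not robustness to every pathology of real Argos data.

With these defaults the end-to-end run reproduces the qualitative
structure of the motivating system — roughly three-quarters of raw fixes
excluded by the home-range filter, a core 50% UD fully contained in the
MPA, and a migrant speed near 18 km/d — without any of those numbers
being targets of the code.

## Numerical choices and limitations

* OU sigma² floored at 1e-6 m² (coincident-fix degeneracy is flagged).
* tau search bounds: [min Δt / 100, 100 × span]; a fit at the lower
  bound is reported as effectively IID.
* KDE renormalization makes each grid integrate to exactly 1; mass
  outside the fixed extent is folded in by that renormalization and
  flagged by the leak warning.
* The 1% sliver guard, 100-m cell, 250-m sweep floor, and Silverman
  start are defaults, not dogma; all are configurable.
* Problem sizes in the test suite (e.g. 100-replicate recovery studies
  at n = 400 OU fixes and 60-day CRW tracks, 10 two-cluster sweep
  geometries) were chosen as the smallest sizes at which the Monte-Carlo
  assertions are stable.
* Containment accuracy is limited by the raster contour (cell-boundary
  polygons); at 100-m cells the discretization error is far below the
  0.1-percentage-point reporting precision.
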