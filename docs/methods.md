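# Methods

## Problem and model family

`walkmet` estimates a COPD patient's submaximal effort tolerance — the MET
score a staged treadmill exercise test would report — from the six-minute
walk test (6MWT).  The 6MWT result is a distance D [m], or equivalently the
average velocity v_6M = D/100 [km/h]; the modeling target is the mapping
M = f(v) from that velocity to the treadmill MET score.

Oxygen uptake grows nonlinearly with power output above the anaerobic
threshold, so a single straight line through the data underfits badly.  Two
nonlinear families are fitted, both anchored at the *generalized MET*
resting condition f(0) = 1 exactly (one MET is the resting energy cost, by
definition of the unit, independent of whether an individual's resting
uptake is 3.5 ml/kg/min):

* **Polynomial expansion** M_pe(v) = 1 + a₁v + … + a_K v^K.  With the unity
  intercept moved to the response this is linear in A = (a₁…a_K) and is
  solved by ordinary least squares of (M − 1) on the interceptless monomial
  basis [v, v², …, v^K].  Default K = 3; orders much higher than that chase
  measurement noise.
* **Continuous piecewise-linear** M_pl(v): n segments with slopes a_j and
  change points V₁ < … < V_{n−1}.  Continuity plus b₁ = 1 determines every
  intercept recursively, b_j = (a_{j−1} − a_j)V_{j−1} + b_{j−1}, so the free
  parameters are the n slopes and n−1 change points.  Default n = 4 because
  rehabilitation practice divides patients into four classes; the model's
  MET values at its change points ("switch points" M⁽ⁱ⁾ = M_pl(V_i)) then
  provide data-driven class boundaries.

The classical linear baseline M₁(v) = 0.5046 v + 1 is kept for negative
comparison, and a small bank of published VO2max(T) treadmill formulas is
shipped for reference; the cubic one's resting offset of 14.76 ml/kg/min
(versus a physiological ~3.5) illustrates the resting-anchor defect the
generalized-MET normalization removes.

## Treadmill conversions

For a fixed-paced protocol with stage durations T_{s,i} and belt velocities
v_i, a walk time T splits into S completed stages plus a partial time δT,
and D = (50/3)·Σ_{i≤S} T_{s,i} v_i + (50/3)·δT·v_{S+1}.  The factor 50/3
(m/min per km/h) is kept as an exact rational; values are rounded to three
decimals only for display.  A walk time exactly on a stage boundary counts
the stage as completed (δT = 0).  The modified-Bruce preset ships stages
1–3 at 2.7 km/h and stage 4 at 4.0 km/h, all 3 min; later stages are
configurable.  Device-reported time→MET scores are tabulated input (the
preset carries the one known pair, 10.5 min → 5.95 MET), not a formula.
Target heart rates use HRmax = 208 − 0.7·age.

## Estimation of the piecewise model

With change points fixed, the continuous model is linear in parameters via
the hinge representation

    M(v) = 1 + a₁v + Σ_{j≥2} (a_j − a_{j−1}) · max(0, v − V_{j−1}),

so the inner problem is an analytic LS solve (`numpy.linalg.lstsq`);
per-segment slopes are cumulative sums of the hinge coefficients.  Only the
change points enter nonlinearly, and the outer search over them uses a
small, fully seeded genetic algorithm:

* real-valued genome = the sorted change-point vector; candidates are
  repaired by sorting, clipping to bounds and enforcing a minimum
  inter-point gap (default 0.3 km/h) so segments stay identifiable;
* tournament selection (size 3), blend crossover (rate 0.7), per-gene
  Gaussian mutation (SD 0.2 km/h, probability 0.2), elitism 2 — so the best
  SSE is non-increasing across generations;
* defaults: population 60, 300 generations, 3 restarts with derived seeds;
  default search interval = [5th, 95th] percentile of observed velocities;
* candidates leaving any segment empty score +∞ (unidentifiable slopes);
* a coordinate-wise bounded scalar polish (golden-section/Brent, xatol
  1e−10) refines the GA optimum; with ~6 polish sweeps noiseless fits
  recover generating parameters to ~1e−7 and RMSE below 1e−8.

`n_segments = 1` short-circuits to the analytic K = 1 polynomial fit.
RMSE always uses 1/N normalization (no degrees-of-freedom correction), and
every stochastic routine takes an explicit seed (default 20180209).  Fits
store the largest training velocity so predictions beyond it can be flagged
as extrapolation.

Tests and the simulation experiments use smaller GA budgets (e.g.
population 30–60, 60–150 generations, 1–2 restarts) sized so a fit takes
well under a second at N ≤ 500; on the grid-search oracle and noiseless
recovery checks these budgets already reach the global optimum, so the
larger defaults buy robustness on messier data, not different answers.

## Cross-validation

Model selection uses leave-one-out CV: refit on N−1 records, predict the
held-out one, summarize with RMSE_cv and the Pearson correlation between
reference and predicted METs.  Piecewise folds re-run the full LS/GA search
with seed = base_seed + fold index; a fixed-change-point mode (slopes-only
refits per fold) exists as a fast option but is not the default, because
reusing full-data change points leaks information and biases RMSE_cv down.
A failing fold aborts the run with its index — folds are never silently
skipped.  Duplicate velocities are left in place; LOO removes exactly one
record per fold.

## Rehabilitation classification

The conventional four-group division is A: M ≥ 7, B: 5 ≤ M < 7,
C: 3 ≤ M < 5, D: 1 < M < 3 (lower bounds closed).  Measured METs at or
below 1.0 are assigned to group D with an explicit below-resting flag
rather than rejected, since near-rest scores occur in severe patients.  A
4-segment fitted model yields the alternative scheme whose boundaries are
its switch points; `scheme_disagreement` reports which records the two
schemes place differently (for the women's reference model, whose
boundaries 2.304/4.094/7.782 differ visibly from 3/5/7).  Sex-specific
schemes are simply parallel scheme objects.

## Synthetic cohorts — what they do and do not show

The generator emulates the structure of the study sample: 299 patients
(159 men, 140 women), ages truncated-normal (mean 56.43, SD 6.13, range
40–65), sex-specific true MET curves defaulting to the reference piecewise
fits, and homoscedastic Gaussian MET noise of SD 0.55 — chosen once to
match the reference fits' residual scatter (RMSE 0.51–0.57).  Velocities
are truncated-normal, mean 5.0 km/h, SD 1.2 km/h, bounds [2.0, 8.5]: the
real joint distribution of (sex, velocity, MET) was never published, so
these are explicitly synthetic-world parameters chosen to span the plotted
data range.  Generated METs are floored at 0.1 (below resting) so
classifier flag paths are exercisable.  Consequently, passing tests
demonstrate correctness of the algorithms under a plausible, well-specified
data-generating process — not agreement with the clinical cohort, whose
heteroscedasticity and velocity distribution may differ.

`recovery_experiment` repeats generate → fit and reports per-parameter bias,
estimate RMSE, Monte-Carlo standard errors and the fraction of replicates
whose change points land within a tolerance (default 0.5 km/h) of truth.
Its GA search interval is widened to the [1st, 99th] velocity percentiles
because the women's first change point (2.68 km/h) lies below the default
5th-percentile bound of the synthetic velocity distribution.

### Known limitation: change-point identifiability under study-level noise

At the emulated study conditions (N = 300, noise SD 0.55) the middle change
point of the women's curve is weakly identified: the slope change across it
(1.415 → 1.99 MET per km/h) is small relative to the noise, and only ~19%
of the velocity mass falls inside the middle segment.  In simulation, the
*global* SSE optimum lands more than 0.5 km/h from the true middle change
point in roughly 40% of replicates — an intrinsic property of the
estimation problem, not an optimizer failure (polishing from the truth
yields a higher SSE in those replicates).  All three change points land
within 0.5 km/h of truth in only ~54% of replicates, and the middle slopes
acquire a positive small-sample bias.  Change-point locations from cohorts
of this size and noise level should therefore be read with wide error bars;
the fitted curve itself (and hence predicted METs) is far more stable, as
the cross-validated RMSE shows.

## Numerical choices

* Exact rational conversion constants (50/3, 3/50); no premature rounding.
* Hinge LS via `lstsq` (minimum-norm solution); a genuinely empty segment
  in a direct `slopes_given_change_points` call warns and falls back to the
  pseudo-inverse, or raises in strict mode.
* Continuity at change points holds to < 1e−9 MET by construction
  (intercepts derived, never stored independently).
* Cohort text files: two columns, whitespace- or comma-separated, optional
  auto-detected header; first-column semantics (meters vs km/h) by explicit
  dialect or the magnitude heuristic (median > 50 ⇒ meters).  Malformed
  lines fail loudly with their line number.
* One top-level pipeline seed; per-stage seeds derived by hashing the stage
  name with it, so a single integer reproduces a whole run.

Out of scope by design: treadmill grade as a second model input, the
exponential uptake model, reverse models D = φ(M), k-fold/information-
criterion model selection, parameter confidence intervals, and any
stochastic (heteroscedastic) error model.
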