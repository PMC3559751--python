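# Methods

## Task geometry and error metrics

The workspace is a horizontal plane with a central start point and six
targets on a circle of radius R = 0.1 m. Target directions are measured in
degrees clockwise from anterior (+y): {90, 210, −30} form the training
set, {0, +120, −120} the unpracticed test set. The perturbation is a 30°
counter-clockwise rotation of the cursor about the start point.

Every hand path is decomposed relative to the ideal straight
start-to-target line into an along-line coordinate r ∈ [0, R] and a signed
perpendicular deviation ε. Sign convention: counter-clockwise of the ideal
line is positive, so errors induced by the CCW rotation are positive and
washout after-effects negative. Two derived quantities:

* **Error profile ε(r)** — ε resampled by linear interpolation onto a
  fixed ascending grid (default 50 points on [0, R]). Because real paths
  can briefly backtrack, interpolation is performed against the running
  maximum (monotone envelope) of r, keeping the most recent sample at each
  envelope value; this makes ε a single-valued function of r and is robust
  to small reversals. Samples beyond the furthest r reached extend as a
  constant. Projections outside [0, R] (overshoot) are clipped to the
  interval.
* **Trajectory error** — the signed perpendicular deviation of largest
  magnitude over all samples, the scalar used throughout the analysis.

## Error augmentation

Augmentation acts only on the perpendicular component of the displayed
cursor; progress along the line toward the target is shown unaltered.

* **Gain**: displayed ε′ = g·ε, with experimental gains 2 and 3.1.
* **Offset**: displayed ε′ = ε + ε_o(r), where the template ε_o(r) is the
  per-target average error profile of the subject's own rotated probe
  trials during baseline (five per training target under the default
  schedule). Templates are frozen once baseline ends. Template lookups at
  arbitrary r use linear interpolation with constant extrapolation beyond
  the grid.

Catch trials retain the rotation but drop augmentation, so all groups are
probed under identical conditions.

## The trial-by-trial learner

The subject's internal model is a single compensation angle θ̂ (degrees
CCW), shared across targets because the rotation is one global transform;
at test targets a generalization factor (default 1, not analyzed) scales
its expression. Each movement:

1. The subject aims compensated by θ̂; with the rotation this leaves an
   effective angular error δ = rotation − θ̂ + η, where η is zero-mean
   Gaussian execution noise.
2. The hand path is a minimum-jerk reach (duration set so that the
   sampled peak speed, drawn from N(0.45, 0.03²) m/s to mimic the task's
   speed feedback window, is attained) with lateral bell deviation
   d·sin(π·r/R), peak d = c·R·sin(δ). The online-correction factor
   c ∈ (0, 1] (default 0.6) captures within-movement corrections that keep
   the endpoint near the target; with δ = 30° it yields the ≈0.03 m
   initial errors characteristic of first exposure.
3. The learner perceives the signed peak deviation d′ of the *displayed*
   path (after augmentation) as the equivalent angle arcsin(d′/(c·R)),
   saturating at ±90° when augmented feedback exceeds the representable
   range, and updates θ̂ ← θ̂ + λ·e_perceived. By default updates occur on
   every trial, including catch and baseline probe trials, from whatever
   error was displayed (whether learning occurs on catch trials is not
   empirically settled; the choice is exposed in `LearnerState`).

For small errors this gives δₖ₊₁ = (1 − λg)·δₖ: monotone convergence for
λg < 1, sign-alternating convergence for 1 < λg < 2, divergence beyond 2.
Because of the arcsin saturation the divergent regime is only realized
while errors remain below the ±90° equivalent; the package's stability
demonstrations therefore probe it at small rotations.

An optional "cautious learner" mode (off by default) shrinks λ whenever
the perceived error exceeds a threshold, a minimal implementation of the
hypothesis that the nervous system down-weights implausibly large errors;
it is provided to illustrate qualitatively why learning can slow at the
×3.1 gain rather than oscillate, and plays no part in the quantitative
benchmarks.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| λ (correction fraction) | 0.32 | – | empirical single-trial compensation fraction for reach trajectory errors |
| rotation | 30 | deg CCW | the studied perturbation |
| c (online correction) | 0.6 | – | reproduces ≈0.03 m initial exposure errors at 30° |
| motor noise SD | 1.5 | deg | calibrated so control catch-series residual RMS about the fitted exponential is ≈0.94 mm (measured 0.94–0.97 mm across seeds; the |error| folding makes residual RMS ≈ 0.6·c·R·σ) |
| peak speed | N(0.45, 0.03²) | m/s | task speed-feedback window 0.45 ± 0.05; logged, not analyzed |
| phases | 165/390/165 | movements | baseline / training / washout |
| catch schedule | 1 per 8 | – | one per complete 8-trial block, never adjacent, shared across subjects |

## What the synthetic data do and do not emulate

The generator reproduces the paradigm's *structure* (schedule, targets,
catch constraints, augmentation transforms, after-effects, trial-to-trial
noise at realistic amplitude) and the *model's* dynamics exactly. It does
not reproduce two features of human data, both consequences of taking the
idealized λ = 0.32 integral learner literally:

* human time constants are 30–52 movements, while a λ = 0.32 learner
  converges with a per-trial factor 0.68 (time constant ≈2.6 movements);
* human steady-state errors plateau at 7–11 mm, while the integral
  learner nulls perceived error — control subjects converge to ≈0 and
  offset subjects overlearn to the −ε_o fixed point.

Tests that pass on simulated cohorts therefore validate the pipeline's
correctness, not the behavioral realism of learning rates. Quantities that
depend on realistic learning-curve shapes (the parameter-recovery
benchmarks) are instead generated directly from the exponential model with
the reference parameter sets evaluated at the schedule's catch positions.

## Curve fitting

Model: e(n) = A·exp(−n/B) + C, n the movement number within phase (time
constants are therefore in movements, commensurate with a 390-movement
training phase). Training-phase series are catch-trial errors; washout
series are all washout movements. Magnitudes |e| are fitted in both
phases: after-effects carry the opposite sign but the model describes the
decay of magnitude.

Minimisation is Nelder-Mead on (A, log B, C) — the log keeps B positive —
with 8 deterministic starts (A₀ from first-minus-last and span; C₀ from
the last point and the mean of the last five; B₀ from N/10, N/3, N with N
the series extent), SSE tolerance 1e-14, one re-polish pass from the
winner, ties broken toward the smallest B. Flat series (|A| < 1e-6 m) are
flagged `identifiable=False` since B is then meaningless; fits where no
start converges are flagged `converged=False`, never silently dropped.
Noiseless self-recovery is exact to ~1e-6 relative; a dense grid search
serves as an independent oracle in the tests.

## Group statistics

Five planned one-way ANOVAs (training A, B, C; washout A, B) driven from
one declarative plan, each followed by Tukey HSD pairwise comparisons at
α = 0.05 and a Kruskal-Wallis check (n = 4 per group is too small to
verify normality). No multiple-testing correction is applied across the
five planned tests. Degenerate inputs use documented conventions: all
groups constant and equal ⇒ F = 0, p = 1; all observations identical ⇒
H = 0, p = 1. Effect size is the equal-n pooled-SD Cohen's d,
|m₁ − m₂| / √((s₁² + s₂²)/2); the percent-reduction summary is the
across-group mean of (initial − steady)/initial.

ANOVA, Tukey and Kruskal-Wallis computations are delegated to
scipy.stats; the test suite checks them against hand-written
sums-of-squares and rank-enumeration oracles.

## Benchmark problem sizes

The recovery benchmarks use 200 replicate series of 48 points each (the
training phase's catch count), noise SD 0.94 mm; the simulated cohort is
the full 4 × 4 design, 720 movements per subject. These sizes make every
benchmark deterministic-given-seed and quick to re-run on a laptop.

## Known limitations

* The learner is a single-state integral model: no retention/forgetting
  term, no trial-to-trial variability in λ, no target-local learning, so
  simulated learning curves are faster and cleaner than human ones (see
  above).
* Return movements, robot/arm dynamics, reaction and movement times, and
  generalization quantification are out of scope.
* The arcsin saturation of perceived error is a modeling convenience for
  feedback that exceeds the representable angular range; behavior in that
  regime (|augmented error| > c·R) should not be over-interpreted.
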