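# Methods

This note documents the models, defaults and numerical choices behind
`pupilnum`, and what the synthetic-data tests do and do not establish.

## Stimulus construction and constraint matching

A stimulus is a set of discs (dots) and rectangles (connecting lines) in
visual degrees on a gray background. Construction follows three steps:
random placement of dots and free lines in a circular field with a 0.5°
minimum clearance between items; pairing of randomly chosen dot couples
into dumbbells; and iterative matching of total ink and convex hull across
conditions.

Decisions taken where the procedure was underdetermined:

* **Connector geometry.** Connectors are drawn edge-to-edge: a flat-capped
  rectangle spanning the gap between the two dot boundaries along the
  center–center axis, with the printed "line length" read as that visible
  gap (2–3° for displaced-lines stimuli, 1.6–2.8° for removed-lines
  stimuli). With this reading the union area is additive (the flat cap is
  tangent to the disc), and the published ink targets (92.7 and 82.3 deg²)
  are reachable with lengths inside the printed ranges — a center-to-center
  reading is not arithmetically consistent with those targets.
* **Pairing.** Random coordinates essentially never place dot couples with
  gaps inside the connector-length range, so `connect_pairs` relocates the
  second dot of each couple next to its partner (gap sampled uniformly in
  range), re-checking clearance; a `move_dots=False` mode pairs fixed
  positions only and raises when infeasible.
* **Placement field.** A circular field of radius 13.5° centered at
  fixation, chosen so the matched hull can reach 513 deg² with modest
  radial scaling.
* **Hull support.** The convex hull is computed over outer ink extents
  (sampled dot boundaries and connector corners), i.e. the covered-area
  reading, not over dot centers.
* **Matching schedule.** The matcher alternates an ink step — uniform line
  lengthening (displaced/connected stimuli) or uniform dot-diameter
  adjustment (removed-lines stimuli) — with a hull step (damped radial
  scaling of item positions about the array centroid), repairing any
  separation violations after each step, until both relative residuals are
  below 0.5 % (default; at most 500 iterations). Ink/position steps are
  nearly orthogonal, so convergence takes a handful of iterations.
* **Ink measurement.** Ink is the exact union area of all shapes
  (shapely), so junction overlap is never double-counted; `rasterize`
  additionally reports a pixel-count area at 20 px/deg, which agrees with
  the exact measure to well under 1 %.
* **Removed-lines diameters.** Isolated dot diameters in experiment 2 are
  computed per-stimulus to absorb the connector ink; the resulting values
  (≈2.41° for 18 dots, ≈2.09° for 24) sit just below the published
  per-dot ranges, consistent with a slightly larger connected-ink figure
  in the original renderer.
* **Spectra.** The radial Fourier amplitude is the modulus of the centered
  2-D DFT of the background-subtracted luminance image, averaged in
  0.1 cyc/deg annuli over 0.3–10 cyc/deg; only the profile shape is
  meaningful (arbitrary units).

## Forward model and synthetic data

Simulated traces are produced by the same linear model the analysis fits:
three unit-integral predictors — onset impulse, offset impulse, sustained
boxcar over the 6 s presentation — convolved with a shifted-Gamma response
kernel and weighted by per-condition β (mm). The condition effect is a
multiplicative gain on the sustained β only; defaults are 0.80 (18
connected), 1.05 (18 isolated), 1.00 (24 connected) and 1.30 (24
isolated), encoding the hypothesis that the response tracks perceived
numerosity, with 18-isolated and 24-connected nearly equivalent. The
sustained β default (0.9 mm, sign negative for white/constriction and
positive for black/dilation) yields plateau amplitudes of ~0.15 mm·gain
and dark-minus-light differences of ~0.2–0.4 mm — the scale seen in real
recordings. Ground-truth kernel defaults (n = 4, τ = 250 ms, δ = 100 ms)
sit comfortably inside the fitting bounds.

Noise is additive AR(1) Gaussian (stationary SD 0.05 mm, per-sample
coefficient 0.995 at 500 Hz): pupil noise is strongly autocorrelated, and
white noise would flatter every validity-weighted estimator. Blinks are
Poisson events (2/min default) with 20 ms linear ramps around a ~0 mm
plateau (100 ms), deliberately shaped to trip both the minimum-size and
velocity exclusion rules. Gaze is white jitter (SD 0.3°) around fixation.
Sessions use a 9 s onset-to-onset interval (1 s fixation + 6 s stimulus +
1 s post + 1 s gap) so that −1…+7 s epochs never share samples.

What the generator does *not* emulate: saccade kinematics, slow
vigilance/arousal drifts, blink-rate differences between conditions,
pupil-size floor/ceiling nonlinearity, and any deviation of the true pupil
response from the assumed LTI Gamma-kernel model. Passing tests therefore
show the pipeline is correct and well-conditioned under its own
assumptions, not that real recordings satisfy those assumptions.

## Preprocessing

Fixed order: artifact masking → 20 Hz bin-average downsampling → 500 ms
square-window filtering → epoching with 200 ms baseline correction.
Exclusion rules: pupil < 0.1 mm; more than 1 mm from the trial median
(computed on the raw trial span, onset−1 s to offset+1 s, before any
masking; outside trial spans the whole-trace median is used); absolute
first-difference rate above 25 mm/s, attributed to both bracketing samples,
each excluding a symmetric ±10 ms window. Excluded samples are dropped,
never interpolated; every downstream mean (bins, filter, baseline, window
statistics, GLM) is validity-weighted.

The stated square-window "high-pass" is implemented literally as a
unit-area moving average (which is a low-pass/smoothing operation); a
subtract-moving-average mode is available behind `filter_mode="subtract"`
but is off by default because it would remove the sustained response the
analysis targets.

## Pupil GLM

τ and δ are in milliseconds (the bounds 10–800 and 0–200 are only
plausible there); conversion to seconds happens once at kernel
construction. n is integer (the kernel uses (n−1)!), enumerated over 1–8
with nested Nelder-Mead over (τ, δ) from 5 quasi-random starts (seeded);
β are profiled out by least squares inside the objective. The sampled
kernel is renormalized to unit discrete mass on the analysis grid, which
only matters when τ approaches the grid step. No intercept is fit: traces
are baseline-corrected, and R² is computed against the uncentered sum of
squares so it stays in [0, 1].

The participant kernel is fit once on the grand-average dark-minus-light
difference trace (averaging raw polarities would cancel the sustained
component) and then frozen for per-condition β fits; all three β are free
per condition. Exact-recovery properties (β to 1e-6; n exact, τ within
5 %, δ within 10 ms) are established on noiseless traces generated on the
analysis grid itself: the 20 Hz bin-averaging smears event timing by up to
half a bin (25 ms) and the 500 ms smoothing reshapes transients, so
recovered δ and the onset/offset β on fully preprocessed data are biased
by design of the preprocessing, while the sustained ordering — the
scientific quantity — is preserved (tested over 100 noisy replicates at
the study's 30 trials per cell).

## Psychometrics and statistics

The cumulative Gaussian is fit by Bernoulli maximum likelihood (correct
binomial weighting at unequal trial counts); the PSE is the fitted median,
so the least-squares/MLE choice does not move it systematically. Lapse is
fixed at 0 by default (a free-lapse option exists). Perfectly separated
(step) data pin σ at a 1e-3 floor with a warning; all-identical responses
raise. Monte-Carlo calibration at the standard design (8 levels × 15
trials, σ = 2): the PSE estimate is unbiased with SE ≈ 0.37 dots, which
fixes what single-observer recovery tests can assert.

The 2×2 repeated-measures ANOVA uses the textbook fully-within
decomposition, each effect tested against its own participant×effect
interaction, with partial η² = SS_effect/(SS_effect+SS_error); Cohen's d
for paired data is mean(diff)/SD(diff). BCEA uses coverage P = 0.68
(field convention; configurable), k = −ln(1−P). Bayes-factor analyses are
deliberately out of scope and the report says so rather than
approximating them.

## Problem sizes

Desk-scale defaults used by the drivers and tests (the library accepts
the full study sizes): 8 simulated participants × 20 trials per session in
the cohort run; 100 replicates × 30 trials per cell for the
condition-ordering property; 200 replicate observers at 8 levels × 15
trials for psychophysics recovery; one seeded stimulus set per experiment
for geometry checks.

## Known limitations

* Per-participant kernels recovered from preprocessed noisy cohorts trade
  τ/δ against the smoothing filter (see above); compare fits on equal
  preprocessing only.
* The matcher can move connector lengths slightly outside the printed
  ranges when the exact ink target demands it (e.g. 24-dot displaced-line
  stimuli need ≈1.99° lines against a 2° nominal minimum).
* `isolate_by_removal` assumes non-overlapping dots when converting ink to
  a per-dot diameter (guaranteed by the separation floor).
* The pipeline fits trial-averaged traces; trial-wise deconvolution with
  overlapping events is out of scope.
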