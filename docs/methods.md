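# Methods

This note documents the models, numerical choices and limitations behind
`cmjump`. Everything quantitative stated here is computed by the test suite
or the example scripts; nothing is quoted from external measurements.

## Signal model and calibration

Both instruments are reduced to a common currency: uniformly sampled
world-vertical acceleration with gravity removed, up positive
(`AccelTrace`). The force platform gives it directly as a = Fz/m − g with the
body mass m taken from the first static second (mean Fz / g, g = 9.81 m/s²
throughout). The smartphone requires more care:

* **Accelerometer calibration** uses three static acquisitions, each with one
  sensor axis aligned with gravity. The model is per-axis offset + scale
  (corrected = (raw − offset)·scale): the off-axis means of the two trials in
  which an axis is not aligned give its offset, and the offset-corrected
  aligned reading is scaled onto g. A full 3×3 misalignment matrix is not
  identifiable from this protocol and is deliberately not attempted.
* **Tilt correction** maps the mean static-phase acceleration vector onto the
  world vertical with a single Rodrigues rotation, then subtracts g. This is
  a static correction: it assumes the phone's orientation changes little
  during ground contact, which holds for a hands-at-waist CMJ but not for
  free arm swings. The gyroscope is used only for bias bookkeeping, not for
  orientation tracking.
* Non-uniform timestamps are linearly resampled to the nominal rate; gaps
  longer than 3 samples abort with a data error. Static-window norms more
  than 10% away from g abort as calibration/posture errors.

## Event detection and height

Onset follows the 8-sigma rule: t0 is 30 ms (rounded to the sample grid)
before the first sample whose magnitude exceeds 8× the static-phase SD.
Take-off is the first sample with a ≤ −g; the search is restarted from the
propulsive acceleration peak so that a deep unweighting dip on a corrupted
trace cannot fire it early. Phase events on [t0, tTO]: the propulsive peak
ta_max is the global argmax of a; the countermovement minimum ta_min is the
argmin *before* ta_max (the take-off sample itself has a ≤ −g and would
otherwise always win); tUB coincides with the velocity minimum; tBP is the
first upward zero crossing of v after it. Ties break to the earliest index.
Events are sample-aligned; intervals are closed.

Velocity is the cumulative trapezoid of a with v(t0) = 0, power is
P = (a + g)·v in W/kg (mass-normalized ground-reaction force times
center-of-mass velocity), and height is h = v²(tTO)/(2g).

**Sub-sample take-off correction.** The first-sample a ≤ −g rule includes
between 0 and 1 sample of free fall in the integral, biasing v(tTO) low by up
to g·Δt — at 128 samples/s that alone is worth up to ~7% of a low jump.
Since the true crossing is uniformly distributed within the final interval,
`measure_jump` adds g·Δt/2 back to the take-off velocity (crossing placed at
the interval midpoint), which zeroes the expected bias and halves the worst
case while leaving the reported event times on the sample grid. With this
correction, noise-free reference jumps across 0.10–0.41 m are recovered
within 1% at 1000 samples/s and within 3% at 128 samples/s (tested).

No pre-filtering is applied before event detection by default; detection
operates on the raw (calibrated, tilt-corrected) trace.

## Variational mode decomposition

The ground-contact segment [t0, tTO] is decomposed into K = 3 band-limited
modes by the standard ADMM scheme: Fourier-domain Wiener-filter mode updates
u_k(ω) = (f − Σ_{i≠k} u_i + λ/2)/(1 + 2α(ω − ω_k)²), center-frequency
updates as spectral centroids, optional dual ascent on the reconstruction
constraint. Defaults: bandwidth penalty α = 2000, dual-ascent step τ = 0 (no
noise amplification), tolerance 1e-7, ≤ 500 iterations, mirror extension at
the boundaries, deterministic center initialization uniformly spaced over
(0, fs/4]. Segments shorter than 64 samples borrow quiet pre-onset samples.
The three central frequencies sorted descending are the features f1 > f2 >
f3; ties (degenerate convergence) raise rather than emit an ill-ordered
vector. On a three-tone test signal the centers are recovered within 0.2 Hz
and the mode sum reconstructs the input within 2% relative L2 (tested).

## Feature set

26 descriptors per jump, computed on [t0, tTO] (samples after take-off have
no influence, tested): the raw height hSP; timings A, C, D, F, G, H, J, M,
O, W; amplitudes/shapes b, e, i, k, p = (e−b)/C, q, r = b/e; velocity s;
powers l, n, u, z; frequencies f1–f3. Conventions that needed fixing:

* **D** is the *interval* from the first positive-acceleration sample after
  tUB to the last one before tTO (interior sign dips included), because the
  shape factor q divides the area under a over that window by the rectangle
  D·e.
* **M** (positive power duration) is the length of the longest contiguous
  run of P > 0 within [t0, tTO] — robust to brief noise-induced sign flips.
* **i** is the maximum central-difference slope of a restricted to
  [ta_min, ta_max], unsmoothed.
* Mean powers u (concentric, [tBP, tTO]) and z (eccentric, [t0, tBP]) are
  trapezoidal time averages.

## Regression stage

The reference height (FP trace, TOV method) is the dependent variable.
Splitting is uniform at random, 75% train (floor rule). Z-score statistics
(sample SD) come from the training split only and are stored for test-time
application; a constant column raises. Lasso at α = 0.1 under the
(1/2n)·RSS + α·‖w‖₁ convention prunes the feature set; survivors have
|coefficient| > 1e-10. **Heights enter the regression in centimetres** — on
the metre scale the same α would shrink every coefficient to zero, so the cm
convention is what makes the stated α meaningful.

The MLP has one hidden layer; the grid is 4 activations (identity, logistic,
tanh, ReLU) × 3 solvers (lbfgs, sgd, adam) × 1–16 hidden units = 192
combinations, each scored by 5-fold shuffled CV on negative MAE;
non-convergent fits are scored as-is with a logged warning. Training
details: max 2000 iterations, initial learning rate 1e-3 (sgd/adam), L2 term
1e-4, weight initialization seeded. The best combination is refit on the
full training split. Bundles serialize to versioned JSON (weights as nested
lists) and reload to bit-identical predictions (tested).

## Evaluation battery

With d = estimate − reference (cm): RMSD, bias, sample-SD precision, MAE ±
SD; these satisfy RMSD² = bias² + ((n−1)/n)·precision² identically. The
heteroscedasticity screen is Kendall's τ — the tie-corrected tau-b variant,
since absolute differences tie readily at cm resolution — between pairwise
means and absolute differences, flagged at τ ≥ 0.1. The paired t-test is
two-sided with dof = n − 1. The calibration regression is OLS of reference
on estimate; SEE is the residual SD with regression dof (n − 2). Bland-Altman
limits of agreement are bias ± 1.96·SD with confidence intervals
t(0.975, n−1)·SD/√n for the bias and t(0.975, n−1)·√(3·SD²/n) for each limit,
plus the average-vs-difference regression and the standardized bias.

Permutation feature importance uses the half-swap scheme: the training rows
are split at random into two halves and the feature's values are exchanged
between them (a permutation that preserves the marginal), the MSE ratio to
baseline is taken, and 10 repeats are averaged. An input the model provably
ignores scores exactly 1.0 (the ratio accumulation is arranged to keep this
exact in floating point).

## Synthetic study conditions

The generator composes the ground-truth center-of-mass acceleration from
half-wave segments — static 0, unweighting dip to b (default −6 m/s², half
sine, 0.35 s), braking/propulsion hump to a peak e (0.30 s), a 40 ms release
ramp to −g, flight at −g, a landing half-sine — with e solved so the net
ground-phase impulse equals √(2·g·h_true) exactly. The FP trace samples this
cleanly at 1000 samples/s. The SP trace samples at 128 samples/s and is
corrupted by: a distortion gain on the ground-contact portion (during flight
the phone is itself in free fall and reads −g regardless of wobble state);
damped sinusoids at 6 and 3.5 Hz (amplitudes 1.2/0.8 m/s², dampings 3/2 s⁻¹,
random phase, ±30% amplitude jitter) starting at movement onset; white noise
(SD 0.15 m/s²); and quantization to the ±8 g, 16-bit grid.

Dataset draws: heights from a truncated normal 25.6 ± 7.4 cm on
[0.10, 0.41] m, body mass 67.5 ± 10.9 kg, per-jump jitter on dip depth and
phase durations. The distortion gain is coupled to height,
gain = 0.90 − 0.50·h_true, so higher jumps are attenuated more — the raw
smartphone height is then biased low with an error that grows with height
(heteroscedastic, as the correction stage must overcome). Default study
size: 200 jumps, a scale at which the full grid search runs in minutes on
one CPU.

**What the generator does not emulate:** musculoskeletal dynamics, arm-swing
kinematic chains, orientation drift during contact, plate-edge artifacts,
and any between-subject structure (jumps are i.i.d. draws, not 4-jump
clusters per participant). Passing the end-to-end tests therefore shows the
pipeline recovers heights under this artifact model, not that the learned
corrector transfers to real handheld recordings.

**A property worth knowing:** because TOV height error is δh ≈ v·δv/g, any
velocity-scale stochastic error (integrated noise, wobble-delayed take-off
detection) produces a height error whose scale grows like √h. Kendall's τ is
scale-free, so with enough test jumps the residuals of *any* TOV-based
estimator on this generator test as heteroscedastic even when they are small
(≈1 cm MAE); at small n the association is usually undetectable. The
corresponding end-to-end assertion in the acceptance tests documents this
honestly rather than hiding it. Relatedly, white sensor noise does not
monotonically degrade the raw height: it dithers the a ≤ −g threshold on the
flight plateau and partially offsets the wobble-induced detection delay, so
the monotone-degradation properties tested are wobble amplitude (mean error)
and noise level (error spread with wobble absent).

## Defaults worth exposing

| parameter | default | unit | why |
|---|---|---|---|
| g | 9.81 | m/s² | fixed convention across all stages |
| onset threshold | 8·σ_static, −30 ms | — | robust to static noise floor |
| VMD α / τ / tol / iters | 2000 / 0 / 1e-7 / 500 | — | short low-rate segments |
| Lasso α | 0.1 | — | cm target scale |
| split / folds | 0.75 / 5 | — | canonical protocol |
| MLP iters / lr / L2 | 2000 / 1e-3 / 1e-4 | — | small-tabular practice |
| PFI repeats | 10 | — | stabilizes half-swap MSE ratios |

All of these are overridable through the library API and the YAML run
configuration used by the CLI.
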