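# Methods

## Problem and model

`habitu` quantifies *physiological habituation* — the decline in the
magnitude of event-locked autonomic responses across repeated exposures to
the same stimulus — and uses it to classify posttraumatic-stress status in
small cohorts. A participant's session consists of an event log (typed
trigger stimuli at known times), raw ECG and skin conductance at 2048 Hz,
pupil diameter at 300 Hz with missing samples marking blinks, and a PCL-M
self-report total (17 items scored 1–5; range 17–85). The binary label is
y = 1 iff PCL-M > 36.

For each event type with at least two valid occurrences, seven features are
computed from the 5-second half-open windows [t, t+5) after the first and
last occurrence:

    stat(series[t0 : t0+5 s]) − stat(series[t_last : t_last+5 s])

with `stat` ∈ {max, min, mean} over heart rate and phasic skin conductance,
plus the eye-blink proxy (EBP): the count of missing pupil samples in the
window. Positive values indicate habituation, negative values
sensitization. The 5-s window accommodates skin-conductance response
latencies of 1–5 s. Intermediate occurrences are ignored: only the two
endpoints enter the feature.

Classification runs under leave-one-out (LOO). Inside every fold, on the
training rows only: features are screened by a two-sided two-sample t-test
at α = 0.05 (Welch variant by default — more robust at ~10 per class;
Student available via `equal_var=True`), missing cells are imputed with the
training mean, columns are z-scored with training parameters (population
SD; constant columns map to 0), and a classifier is fitted. The default is
a Gaussian-process classifier with a constant × RBF kernel whose
hyperparameters are tuned by seeded multistart maximization of the
Laplace-approximate marginal likelihood (`search_budget` starts, default
8). KNN, random forest, decision tree, logistic regression, MLP and
soft/hard voting ensembles are available under the same interface. If no
feature passes screening the fold falls back to the single smallest-p
feature (logged); this occurs only in degenerate, near-null cohorts. The
reported metric is the average held-out accuracy, with TPR/TNR, confusion
counts, a probability-sweep ROC, and the majority-class baseline.

## Attributions and the habituation response

Per-fold feature attributions are interventional Shapley values on the
classifier's PTSD-probability output, with the fold's training rows as the
background distribution (the only leakage-free choice). A coalition's
value is the background-mean output with coalition features set to the
explained participant's values. With ≤ 12 selected features the full
coalition lattice is enumerated (exact); otherwise a seeded
permutation-sampling estimator with antithetic pairs is used. Both satisfy
base + Σφ = f(x) exactly; the implementation raises if the identity is
violated beyond 1e-6 relative. Attributions act on probabilities rather
than log-odds; this is a documented choice, switchable by attribuing a
different output functional.

Global importance is the cumulative |φ| per (event type × marker) pair
across participants, and per marker group.

The individual habituation response is

    response = Σ_i x_i · |w_i|

over the fold's selected features, where x_i is the *raw* (unscaled)
habituation feature value (imputed cells contribute their train-mean
imputation) and w_i its Shapley value. Raw values are used so the response
keeps physiological sign and units; a scaled variant is a one-line change
at the call site. The response is regressed (OLS) against the PCL-M score;
a positive slope means stronger habituators report more symptoms.

## Signal preprocessing

* **ECG → HR.** R peaks by thresholded local-maximum detection (99.9th
  percentile × 0.5 height, 50 ms minimum spacing). Inter-beat intervals
  outside [0.33, 2.0] s are treated as artefacts: spuriously short
  intervals are removed by dropping the offending peak, overlong ones by
  interpolating the beat-wise rate across the gap. HR = 60/IBI is linearly
  interpolated to the native grid, held constant beyond the first/last
  beat, then decimated to 32 Hz.
* **EDA decomposition.** Skin conductance is split into tonic + phasic by
  a convex program: ½‖y − Kq − Bc‖² + α·Σq + ½λ‖D₂c‖², with q ≥ 0 a sparse
  sudomotor driver convolved with a Bateman biexponential kernel
  (τ = 0.7 s / 3.0 s, truncated at 15 s), B a linear-interpolation tonic
  basis with knots every 10 s, and D₂ the knot-curvature penalty.
  Defaults α = 0.1, λ = 10 (chosen so that single SCRs of ~0.1 µS are
  captured while measurement noise is not). Because the L1 term is linear
  under the nonnegativity bound, the problem is a smooth bound-constrained
  QP solved with L-BFGS-B (≤ 300 iterations; non-convergence raises). The
  driver lives on an 8 Hz grid (0.125 s resolution — far finer than the
  0.5 s peak-time accuracy the window features need) to keep the solve
  fast. Decomposition runs *after* downsampling to 32 Hz; the window
  statistics downstream are insensitive to this ordering and the program
  scales with sample count.
* **Downsampling.** Polyphase anti-aliased decimation (`resample_poly`,
  line-extension padding) to 32 Hz; output length floor(duration × 32).
  For the pupil channel, missing samples are linearly bridged before
  filtering and an output sample is marked missing iff a strict majority
  of its source window is missing.
* **Event cleaning.** Zone-withdrawal occurrences (no physiological
  stimulus) are removed; remaining occurrences are time-sorted.
  Occurrences whose 5-s window overruns the recording, or whose window has
  < 80% pupil coverage, are invalid; first/last are recomputed over valid
  occurrences and event types with < 2 valid occurrences emit no features.
  Participants with empty feature vectors are dropped with a logged
  reason; assembly requires ≥ 4 usable participants.

## Synthetic cohort

Because comparable clinical recordings are access-restricted, the
generator is first-class, tested code that defines the study conditions:

* ~21 participants, session length drawn from Normal(7.86, 1.83) minutes
  truncated to [5, 15]; 4 stimulus event types (explosion, flashbang,
  tank_fire, dog_bark) × 3 occurrences plus 2 zone-withdrawal events,
  packed with ≥ 6 s between consecutive events and ≥ 5 s margins.
* Response amplitudes follow an exponential habituation law
  A_k = A₀·exp(−g·k) for occurrence k, the simplest monotone law
  consistent with the habituation/sensitization definition. Defaults:
  A₀ = 0.6 µS (phasic), 12 bpm (HR), 8 missing 32 Hz frames (blink gap).
* Kernels: SCR = t·e^(−t/1.5)·sin(πt/6) on [0, 6) s (peak ≈ 1.4 s, within
  the 1–5 s latency band); HR bump = raised cosine on [0, 4] s. Both are
  compact-support and peak-normalized on the 32 Hz grid, and scenario
  times are snapped to that grid, so with the ≥ 6 s gap the windowed
  maximum recovers the injected amplitude to machine precision. Blink
  gaps span whole 32 Hz frames, making the EBP an exact integer. The
  decomposition deliberately uses a *different* (Bateman) kernel, so the
  signal-prep path is exercised under realistic model mismatch.
* Raw channels on top of the ground truth: ECG as a stereotyped
  QRS+T-wave template placed at beats obtained by integrating the
  instantaneous rate; tonic drift + SCR train + white noise for skin
  conductance; pupil diameter with Poisson background blinks
  (lognormal durations, mean ≈ 0.2 s) and additive noise.
* Cohorts: n_pos = round(n·10/21) positives (10:11 at n = 21). The class
  separation knob `effect` is the distance between class-mean habituation
  gains in within-class SD units (SD 0.15); positives draw positive gains
  (habituation), negatives nonpositive (sensitization), with no sign
  enforcement at effect = 0 so the null cohort is exchangeable. PCL-M is
  positively coupled to the gain (36.5 + 20g + N(0, 3), rounded, clamped
  to the class side of 36), so the response–severity relationship is
  recoverable.

What the generator does not emulate: real beat-morphology variability,
motion artefacts, electrode drift and detachment, respiratory/HRV
structure, gaze-dependent pupil size, or event-type-specific salience.
Passing tests therefore demonstrate the pipeline's correctness and its
power under the modeled effect structure, not clinical performance.

## Problem sizes in the test suite

Statistical suites are sized to keep a single-CPU run short while leaving
ample power: classification power uses 20 cohorts of n = 21 through the
full raw-signal path; the type-I check uses 1000 null features on one
n = 21 null cohort; the regression-direction check uses 50 cohorts of
n = 12 on the generator's ground-truth signal path (which skips raw-signal
synthesis, not any analysis stage); the permutation null uses 500
shuffles. Unit fixtures use 150–300 s sessions.

## Known limitations

* The EDA program's regularization weights are fixed defaults, not
  per-recording tuned; heavily drifting tonic levels can leak into the
  phasic estimate (bounded by the 5%-of-range residual check).
* The GP hyperparameter search optimizes marginal likelihood, not
  cross-validated accuracy; with ~20 training rows this is the stabler
  criterion but can underfit deliberately adversarial feature sets.
* With fewer than ~3 participants per class, fold-internal screening can
  find no testable feature and the fold fails loudly rather than guess.
* The decision threshold is 0.5 by default; the ROC artifact exists
  precisely so users can trade TPR against FPR, and the threshold is a
  config field.
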