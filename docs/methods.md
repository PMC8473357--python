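# Methods

This note documents the models and procedures implemented in `gaitfusion`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic experiments show.

## The pipeline

### Filtering

Raw sEMG is band-passed 30–300 Hz and linear acceleration low-passed at
25 Hz, both with zero-lag (forward–backward) Butterworth filters.  "Order"
is the *total effective* order of the combined two-pass magnitude
response — the usual convention in gait analysis — so the order-4 EMG
band-pass is a 2nd-order design applied twice, and the order-6
acceleration low-pass a 3rd-order design applied twice.  Edge transients
are suppressed with reflective padding of three times the filter length;
signals shorter than the pad are rejected rather than silently filtered.

### Gait segmentation

Heel strikes are local maxima of the heel-minus-pelvis anterior
coordinate, with a prominence threshold of 25 % of the coordinate's range
(configurable) and a 0.4 s refractory interval.  Gait cycles are half-open
intervals `[HS_i, HS_{i+1})`; the half-open convention makes the "label
switches exactly at a heel strike" case unambiguous (the preceding cycle
stays steady).  A cycle whose label track contains a switch is a *gait
transition*, carrying the mode reached at its end.  Transition ground
truth comes from the simulator's label track (or user-supplied terrain
labels); a kinematic transition criterion from hip angular velocity would
require parameters that are not available, so it is deliberately not
guessed at.

### Features

The feature at instant *i* is the RMS of each preprocessed channel over
the trailing window (default 80 ms = 160 samples at 2000 Hz), assembled
as 14 EMG values followed by 21 acceleration values.  Windows are
*end-anchored*: the decision at time *t* uses only samples ≤ *t*.  A
centred window would leak future samples and corrupt every response-time
measurement, which is why causality is enforced down to the arithmetic:
the moving mean-square uses direct convolution, where each output depends
on exactly its own window (an FFT-based scheme couples outputs at the
1e-12 level, enough to fail a strict causality check).

Min–max normalisation bounds are learned on training folds only and
applied to held-out data with clipping to [−0.5, 1.5] to bound
extrapolation.  Fitting bounds per training fold (rather than over all
data) is the leakage-safe reading of "normalised over all activities";
the alternative would let test extrema influence the feature scale.

The online stream advances one sample (0.5 ms) per decision.  For
*training*, consecutive rows 0.5 ms apart are almost duplicates, so
training rows are subsampled by a stride (default 20; cohort-scale runs in
the acceptance script use 100) — the stride changes the training-set
density only, never the feature definition or the online step.

### Classifiers

SVM (RBF kernel, C-SVM, one-vs-one), KNN, LDA and a feed-forward network
with one hidden layer of 30 nodes.  Backends are scikit-learn; the
package's contribution is the protocol around them.  Hyperparameters are
tuned by stratified five-fold cross-validated grid search: C ∈ 2^{−5..15},
γ ∈ 2^{−15..3} (exponent step 2) for the SVM, odd k ∈ 1..25 for KNN.
Cohort-scale experiment configurations use a coarser 3×3 SVM grid
(C ∈ {1, 16, 256}, γ ∈ {2⁻⁵, 2⁻², 2}), which on the synthetic features
selects within one grid step of the full search at a fraction of the
cost.  LDA is plain linear discriminant analysis — a kernelised variant
would contradict the name and no kernel parameters exist to honour.  The
ANN trains with full-batch Nesterov-momentum gradient descent (learning
rate 0.01, momentum 0.9, up to 2000 epochs with plateau early-stopping);
the epoch budget is what full-batch descent at this learning rate needs
to separate the seven modes cleanly.

Models train on **steady-state rows only**: transition-cycle rows are
excluded before fitting, so any correct early naming of the next mode
during a transition is genuine extrapolation, not memorised transition
data.  Trials are split 5:1 (with 30 trials per task: 25 train / 5 test),
reproducibly under a seed; held-out trials influence neither the
normalisation bounds nor the hyperparameter choice.

### Online decision layer

The raw per-sample stream is stabilised by two rules:

* **Agreement vote** — the output switches to mode *m* only when the last
  `agreement_n` raw labels (default 100, inclusive of the current instant)
  all equal *m*.  At 2000 Hz this is a 50 ms minimum recognition delay.
  The vote counts *consecutive* agreement on the raw-stream suffix, which
  keeps the operator memoryless beyond `agreement_n` labels: a candidate
  blocked by the legality rule accumulates no hidden credit and must
  re-earn agreement if it later becomes legal.  (A 100-of-M majority
  variant would be a config change; consecutive agreement is the reading
  consistent with the stated 50 ms delay.)
* **Transition legality** — updates must be legal under a 7×7 rule table:
  sit ⇄ stand, stand ⇄ level walk, level walk to anything except sit, and
  stair/ramp modes only back to level walk (18 allowed cells including the
  diagonal).  The table is asymmetric (sit → stand is legal, stand → sit
  is not).

The initial output mode is taken from the trial's first ground-truth label
(trials start seated or standing); bootstrapping the initial state from
the vote itself would leave the output undefined for the first samples.

### Metrics

Steady-state performance is scored sample-wise over steady cycles only:
CA = 100·N_true/N_all, plus per-mode one-vs-rest sensitivity and
specificity, macro-averaged over the modes present (modes with no true
samples in a trial are excluded from the macro mean rather than scored 0).

Prediction is scored **per transition event**, one response time per
transition: T_actual is the heel strike starting the next steady mode, and
T_pred the earliest time within the transition cycle at which the output
equals the upcoming mode *and stays there until T_actual* — a transient
flicker cannot claim a large negative RT.  A transition whose mode is only
recognised after its onset still counts as correct, with RT > 0; one whose
mode never appears on the output during the transition or its steady
segment counts against PA and contributes no RT.  With no transitions in
the data PA is reported as absent, not zero.

## The synthetic-data generator

Real recordings of this protocol are not publicly deposited, so the
simulator is the test substrate.  It reproduces the *structure* the
pipeline relies on, not muscle physiology:

* **EMG** = mode- and phase-specific activation envelope × band-limited
  (30–300 Hz) unit-variance Gaussian carrier + wide-band noise floor
  (envelope-to-noise ratio 20:1 by default).  This matches the RMS-feature
  assumption: the sliding RMS of the signal tracks the envelope.
  Envelopes are hand-designed per (mode, muscle): a tonic level plus a
  raised-cosine burst locked to gait phase, with the left leg half a cycle
  out of phase.  A deterministic tonal carrier (`carrier="tone"`) is
  available for noise-free limit checks.
* **Acceleration** = constant gravity projection per segment orientation
  (mode-specific pitch) + one- and two-per-cycle harmonics + Gaussian
  noise (SD 0.5 m/s², an intentionally non-trivial sensor/soft-tissue
  noise level).  Orientation offsets carry the mode information a real
  IMU montage would.
* **Markers** — the heel-minus-pelvis anterior coordinate is a cosine of
  the gait phase, peaking exactly at heel strikes, which is what the
  coordinate-based detector assumes.
* **Timing** — consecutive steady segments (default 4 cycles of
  1.1 s ± 5 % jitter each) are bridged by one transition cycle.  The
  ground-truth label switches at its midpoint; the `mode_onset` event (and
  the acceleration templates) switch at the heel strike ending it; the EMG
  envelopes switch `emg_lead_ms` earlier (default 300 ms, a typical
  anticipatory-activation interval).  Switches are linear cross-fades over
  `ramp_ms` (default 100 ms) *starting at the switch time*, so the first
  envelope deviation from the old template occurs exactly `emg_lead_ms`
  before the onset — hard switches would make timing exact too, but would
  inject filter ringing into the feature stream.
* Quasi-static modes (sit, stand) keep nominal pseudo-cycles in the marker
  traces so the cycle machinery applies uniformly across the script.

Everything is driven by one seed; identical configurations give
bit-identical trials.

### What the synthetic experiments show — and don't

On this substrate the full pipeline recovers the designed structure: fused
and EMG-only models name the next steady mode before its onset (mean RT ≈
−125 ms for the fused SVM: the 300 ms lead minus the 50 ms vote latency,
the 80 ms window fill and part of the cross-fade), acceleration-only
models recognise it only afterwards (RT ≈ +90 ms), and fusion's
steady-state accuracy is at least that of acceleration alone.  These are
checks of *mechanism*, not forecasts of accuracy on people: the
between-mode template margins are free design parameters, so absolute
synthetic accuracies (near-ceiling here) are not comparable to accuracies
on human data, where electrode placement, cross-talk, fatigue and
inter-subject variability dominate.  What carries over is the ordering
and sign structure: any online system whose EMG features lead its
kinematic features by Δt, filtered through an RMS window w and a vote of
n samples, can at best report a transition around Δt − w − n/fs before
onset.

The accel-only pipeline cannot reach 100 % steady-state accuracy even
noise-free: its features switch at the onset itself, so the vote layer's
latency bleeds misclassified samples into the start of each new steady
segment.  This is a property of the method, visible in the tests.

## Numerical and degenerate-input choices

* Constant feature columns normalise to zero with a warning rather than
  dividing by zero; held-out features clip to [−0.5, 1.5].
* Constant marker traces yield "no heel strikes", an empty result, not an
  error; fewer than two events yield no cycles.
* `sliding_rms` clamps tiny negative mean-squares (floating-point) to zero
  before the square root.
* Scripted task configurations are validated against the transition-rule
  table up front; an illegal script fails naming the offending pair.
* Cohort runs in tests and the acceptance script use 4–6 trials per task,
  2–4 cycles per steady segment and a training stride of 100–150: the
  smallest sizes at which every scripted transition type is exercised with
  a 5:1 trial split.

## Known limitations

* Templates are phase-locked curves, not musculoskeletal output; no motion
  artefacts, powerline interference or electrode-shift effects are
  modelled.
* One transition cycle bridges each pair of steady segments; multi-cycle
  hesitant transitions are out of scope.
* The decision layer is deliberately memory-light (vote + rule table); no
  probabilistic smoothing (HMM/Bayes filtering) or gait-phase-dependent
  classifier switching is included.
* ANOVA/post-hoc comparisons across classifiers are routine statistics
  left to standard tools around the exported tidy tables; they are not
  part of the package API.
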