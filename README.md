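# gaitfusion

Online locomotion-mode **recognition and prediction** from fused surface
electromyography (sEMG) and linear-acceleration signals, for human-movement
analysis and neurorehabilitation research (exoskeleton / prosthesis
high-level control, gait labs, intent-detection studies).

Inertial signals describe the body's *current* mechanical state; muscle
activation precedes the movement it drives.  `gaitfusion` implements an
online pipeline that exploits this: classifiers trained **only on
steady-state gait** can name the *next* steady locomotion mode during a
gait transition, before that mode actually begins.

## The method

Seven locomotion activities are distinguished: sit (S), stand (ST), level
walk (LW), stair ascent/descent (SA/SD), ramp ascent/descent (RA/RD).
Trials are multi-channel recordings at 2000 Hz: 14 sEMG channels (7 lower
limb muscles x both legs), 21 acceleration channels (pelvis, thighs,
shanks, feet x 3 axes) and anterior marker traces for gait-event detection.

1. **Preprocessing** — zero-lag Butterworth filters: EMG band-pass
   30–300 Hz (total order 4), acceleration low-pass 25 Hz (total order 6).
2. **Segmentation** — heel strikes at local maxima of the heel-minus-pelvis
   anterior coordinate (coordinate-based detection); gait cycles are the
   half-open intervals between consecutive ipsilateral strikes; a cycle
   containing a mode switch is a *gait transition*.
3. **Features** — at every sample instant *i*, the causal sliding-window
   RMS of each channel, min–max normalised with training bounds, fused into

   X_i = {T_e1 … T_e14, T_a1 … T_a21}  (35 values).

4. **Classification** — SVM (RBF, one-vs-one), KNN, LDA or a small ANN
   (30 hidden nodes), tuned by five-fold cross-validated grid search and
   trained on steady-state rows only.
5. **Online decision** — the raw per-sample stream updates the reported
   mode only when ≥100 consecutive labels agree (50 ms at 2000 Hz) *and*
   the (previous, next) pair is legal under a transition-rule table
   (S↔ST↔LW hub; stairs/ramps connect only through LW).
6. **Evaluation** — steady-state classification accuracy CA = N_true/N_all,
   per-mode one-vs-rest sensitivity/specificity (macro-averaged), and per
   transition the predictive accuracy PA and response time
   RT = T_pred − T_actual (negative ⇒ the mode was named before it began).

Because matched human recordings are not publicly deposited, the package
ships a first-class synthetic-trial generator (`gaitfusion.simulate`) that
emulates the seven modes, the five scripted daily-living tasks, the
band-limited EMG carrier and — crucially — a configurable interval by which
the EMG envelopes lead the kinematic change at every transition (default
300 ms), making the prediction claim testable end to end.

## Worked example

`examples/04_predict_transitions.py` simulates six stand–walk–stairs–walk–
stand trials, trains an SVM on steady-state rows of five of them, and
streams the held-out trial through the decision layer:

```
steady-state CA = 100.00 %   (SE 100.00 %, SP 100.00 %)
predictive accuracy PA = 100.0 % over 4 transitions
mean response time RT = -130.5 ms (negative = predicted before onset)

  -> LW at   6.03 s   RT   -150.5 ms
  -> SA at  11.67 s   RT   -129.0 ms
  -> LW at  17.25 s   RT   -119.0 ms
  -> ST at  22.75 s   RT   -123.5 ms
```

Every upcoming steady mode was on the output stream 119–151 ms before its
first heel strike: the 300 ms activation lead, minus the 80 ms RMS window
fill, the 50 ms vote latency and the envelope cross-fade.
`examples/05_modality_comparison.py` repeats this per data type — with
acceleration alone the response time is **positive** (+119 ms, recognition
after the fact), with EMG present it is negative; fusion also lifts
steady-state accuracy (100 % vs 97.8 % accel-only on this cohort).

The other examples cover simulation and trial IO (`01`), preprocessing,
segmentation and features (`02`), and the vote/legality layer (`03`).
A thin CLI wraps the cohort-level runs:

```bash
gaitfusion simulate --task 2 --seed 7 --emg-lead-ms 300 --out trial.tsv
gaitfusion compare-modalities --task 2 --seed 1
gaitfusion run my_experiment.yaml
```

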