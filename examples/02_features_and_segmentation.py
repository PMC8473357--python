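"""Preprocess a trial, detect heel strikes, and build the fused features.

Shows the standard signal path: zero-lag Butterworth filtering (EMG
30-300 Hz order 4, accel 25 Hz order 6), coordinate-based heel-strike
detection, gait-cycle labelling, and the causal 35-element sliding-RMS
feature stream.
"""

from gaitfusion import (SimulationConfig, build_features, detect_heel_strikes,
                        preprocess_trial, segment_cycles, simulate_trial)

trial = simulate_trial(SimulationConfig.for_task(2, seed=1, n_cycles_per_mode=2))
clean = preprocess_trial(trial)

hs = detect_heel_strikes(trial.markers[0], trial.markers[2], trial.fs)
cycles = segment_cycles(hs, trial.truth_labels, trial.fs)
print(f"{len(hs)} heel strikes -> {len(cycles)} gait cycles "
      f"({sum(c.is_transition for c in cycles)} transitions)")
for c in cycles[:6]:
    label = "TRANSITION->" + c.next_mode.name if c.is_transition else c.mode.name
    print(f"  [{c.start_s:6.3f}, {c.end_s:6.3f}) s  {label}")

fm = build_features(clean, window_ms=80.0)
print(f"feature matrix: {fm.X.shape[0]} instants x {fm.X.shape[1]} features "
      f"(window {fm.window_ms:.0f} ms = {int(fm.window_ms/1000*trial.fs)} samples)")
print("first columns:", ", ".join(fm.channel_names[:4]), "...")
# Each row is the RMS of the trailing 80 ms of every channel: an amplitude
# proxy for muscle activation (EMG) and segment motion (acceleration).
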