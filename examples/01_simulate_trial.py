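"""Simulate one locomotion trial and inspect its structure.

Generates a stand -> level walk -> stair ascent -> level walk -> stand
trial (task 2) with a 300 ms EMG activation lead, prints the event
timeline, and writes the trial to disk as TSV + JSON sidecar.
"""

from gaitfusion import SimulationConfig, simulate_trial, write_trial

cfg = SimulationConfig.for_task(2, seed=1)
trial = simulate_trial(cfg)

print(f"trial: {trial.n_samples} samples at {trial.fs:.0f} Hz "
      f"({trial.duration_s:.1f} s)")
print(f"channels: {trial.emg.shape[0]} EMG, {trial.accel.shape[0]} accel, "
      f"{trial.markers.shape[0]} markers")
print(f"heel strikes: {len(trial.heel_strike_times())}")
print("mode onsets (the actual starts of each steady mode):")
for ev in trial.mode_onsets():
    print(f"  {ev.time_s:7.3f} s -> {ev.mode.name}")

write_trial(trial, "scratch_trial.tsv")
print("wrote scratch_trial.tsv (+ .json sidecar)")
# The EMG envelopes switched to each upcoming mode 300 ms before these
# onsets; the accelerations switched at the onsets themselves.
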