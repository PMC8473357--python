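"""The synthetic-trial generator: determinism, timing and signal structure."""

import math

import numpy as np
import pytest
from scipy import signal as sps

from gaitfusion import SimulationConfig, mode_templates, read_trial, simulate_trial, write_trial
from gaitfusion.modes import TASK_SCRIPTS, LocomotionMode
from gaitfusion.simulate import _emg_envelope_at


class TestModeTemplates:
    def test_shapes_and_determinism(self):
        emg, acc = mode_templates(LocomotionMode.LW, 100)
        emg2, acc2 = mode_templates("LW", 100)
        assert emg.shape == (14, 100) and acc.shape == (21, 100)
        np.testing.assert_array_equal(emg, emg2)
        np.testing.assert_array_equal(acc, acc2)

    def test_sitting_is_quasi_static(self):
        emg, acc = mode_templates(LocomotionMode.S, 128)
        assert emg.max() < 0.05                       # near-baseline activation
        assert np.allclose(acc, acc[:, :1])           # constant gravity projection

    def test_emg_envelopes_nonnegative(self):
        for mode in LocomotionMode:
            emg, _ = mode_templates(mode, 64)
            assert emg.min() > 0

    @pytest.mark.parametrize("m1", list(LocomotionMode))
    @pytest.mark.parametrize("m2", list(LocomotionMode))
    def test_mode_distinctness_margin(self, m1, m2):
        """Any two modes differ in some channel by more than the default
        noise levels (EMG wide-band SD 0.05; accel SD 0.5)."""
        if m1 == m2:
            return
        e1, a1 = mode_templates(m1, 100)
        e2, a2 = mode_templates(m2, 100)
        emg_margin = np.abs(e1 - e2).max()
        acc_margin = np.abs(a1 - a2).max()
        assert emg_margin > 0.05 or acc_margin > 0.5

    def test_unknown_mode_and_small_n_error(self):
        with pytest.raises(ValueError, match="unknown locomotion mode"):
            mode_templates("XX", 100)
        with pytest.raises(ValueError, match="n_points"):
            mode_templates(LocomotionMode.LW, 4)


class TestSimulateTrial:
    def test_seeded_determinism(self):
        cfg = SimulationConfig.for_task(1, n_cycles_per_mode=2, seed=11)
        a, b = simulate_trial(cfg), simulate_trial(cfg)
        np.testing.assert_array_equal(a.emg, b.emg)
        np.testing.assert_array_equal(a.accel, b.accel)
        np.testing.assert_array_equal(a.markers, b.markers)
        np.testing.assert_array_equal(a.truth_labels, b.truth_labels)
        assert a.truth_events == b.truth_events

    def test_illegal_script_rejected_naming_pair(self):
        with pytest.raises(ValueError, match="S->LW"):
            SimulationConfig(task_script=(LocomotionMode.S, LocomotionMode.LW))

    def test_all_five_task_scripts_are_legal(self):
        for task in TASK_SCRIPTS:
            SimulationConfig.for_task(task)   # must not raise

    @pytest.mark.parametrize("lead_ms", [0.0, 300.0])
    def test_emg_lead_timing(self, lead_ms):
        """The first sample where the EMG envelope deviates from the
        old-mode template precedes the mode onset by exactly the configured
        lead (0 -> switches coincide; 300 ms at 2 kHz -> 600 samples +/- 1)."""
        cfg = SimulationConfig.for_task(2, n_cycles_per_mode=2, seed=2,
                                        emg_lead_ms=lead_ms)
        ref = SimulationConfig.for_task(2, n_cycles_per_mode=2, seed=2,
                                        emg_lead_ms=0.0, ramp_ms=cfg.ramp_ms)
        trial = simulate_trial(cfg)
        trial0 = simulate_trial(ref)
        fs = cfg.fs
        expected_lead = int(round(lead_ms / 1000 * fs))
        for ev in trial.mode_onsets():
            i_on = int(round(ev.time_s * fs))
            # zero-lead envelope equals the old-mode template up to onset
            start = i_on - int(1.0 * fs)
            diff = np.abs(trial.emg_envelope[:, start:i_on + 1]
                          - trial0.emg_envelope[:, start:i_on + 1]).max(axis=0)
            dev = np.flatnonzero(diff > 1e-12)
            if expected_lead == 0:
                assert dev.size == 0
            else:
                first = start + dev[0]
                assert abs((i_on - first) - expected_lead) <= 1

    def test_accel_switches_at_onset(self, trial_small):
        """Clean accelerations equal the old-mode pattern until mode onset."""
        fs = trial_small.fs
        cfg0 = SimulationConfig.for_task(2, n_cycles_per_mode=2, seed=3,
                                         emg_lead_ms=0.0)
        trial0 = simulate_trial(cfg0)
        for ev in trial_small.mode_onsets():
            i_on = int(round(ev.time_s * fs))
            seg = slice(i_on - 400, i_on)
            np.testing.assert_allclose(trial_small.accel_clean[:, seg],
                                       trial0.accel_clean[:, seg], atol=1e-12)

    def test_heel_strike_count_and_marker_maxima(self, trial_small):
        cfg = trial_small.config
        n_cycles = (cfg.n_cycles_per_mode * len(cfg.task_script)
                    + len(cfg.task_script) - 1)
        hs = trial_small.heel_strike_times()
        assert len(hs) == n_cycles + 1
        # (heel - pelvis) attains a local maximum within 5 ms of each strike
        rel = trial_small.markers[0] - trial_small.markers[2]
        peaks, _ = sps.find_peaks(rel, prominence=0.1)
        peak_t = peaks / cfg.fs
        for h in hs:
            assert np.abs(peak_t - h).min() <= 0.005

    def test_labels_switch_once_per_transition(self, trial_small):
        changes = np.flatnonzero(np.diff(trial_small.truth_labels))
        assert changes.size == len(trial_small.mode_onsets())

    def test_emg_carrier_band_limited(self, trial_small):
        """>= 90% of EMG power lies in the 30-300 Hz carrier band during an
        active steady segment."""
        fs = trial_small.fs
        onsets = [e.time_s for e in trial_small.mode_onsets()]
        # middle of the first LW segment
        i0 = int((onsets[0] + 0.5) * fs)
        seg = trial_small.emg[5, i0:i0 + 4096]        # MG_R, strongly active in LW
        f, p = sps.periodogram(seg, fs=fs)
        band = (f >= 30) & (f <= 300)
        assert p[band].sum() / p.sum() >= 0.90


class TestTrialIO:
    def test_roundtrip_lossless(self, tmp_path, trial_tiny):
        path = tmp_path / "trial.tsv"
        write_trial(trial_tiny, path)
        back = read_trial(path)
        np.testing.assert_allclose(back.emg, trial_tiny.emg, atol=1e-9)
        np.testing.assert_allclose(back.accel, trial_tiny.accel, atol=1e-9)
        np.testing.assert_allclose(back.markers, trial_tiny.markers, atol=1e-9)
        np.testing.assert_array_equal(back.truth_labels, trial_tiny.truth_labels)
        assert back.fs == trial_tiny.fs
        assert len(back.truth_events) == len(trial_tiny.truth_events)
        assert back.config == trial_tiny.config

    def test_channel_count_mismatch_rejected(self, tmp_path, trial_tiny):
        import json

        path = tmp_path / "trial.tsv"
        write_trial(trial_tiny, path)
        sidecar = path.with_suffix(".json")
        doc = json.loads(sidecar.read_text())
        doc["channels"]["emg"] = doc["channels"]["emg"][:13]
        sidecar.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="channel-count mismatch"):
            read_trial(path)

    def test_missing_events_key_rejected(self, tmp_path, trial_tiny):
        import json

        path = tmp_path / "trial.tsv"
        write_trial(trial_tiny, path)
        sidecar = path.with_suffix(".json")
        doc = json.loads(sidecar.read_text())
        del doc["events"]
        sidecar.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="events"):
            read_trial(path)

    def test_malformed_sidecar_rejected(self, tmp_path, trial_tiny):
        path = tmp_path / "trial.tsv"
        write_trial(trial_tiny, path)
        path.with_suffix(".json").write_text("{not json")
        with pytest.raises(ValueError, match="malformed sidecar"):
            read_trial(path)
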