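"""Steady-state metrics, transition scoring, and their oracles."""

import numpy as np
import pytest

from gaitfusion import score_steady, score_transitions
from gaitfusion.decision import DecisionTrace
from gaitfusion.modes import N_MODES, LocomotionMode
from gaitfusion.segmentation import Transition

M = LocomotionMode


def tally_metrics(truth, pred):
    """Independent brute-force per-class tally of CA/SE/SP."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    ca = 100.0 * np.mean(truth == pred)
    se, sp = [], []
    for i in range(N_MODES):
        tp = int(np.sum((truth == i) & (pred == i)))
        fn = int(np.sum((truth == i) & (pred != i)))
        fp = int(np.sum((truth != i) & (pred == i)))
        tn = int(np.sum((truth != i) & (pred != i)))
        se.append(100.0 * tp / (tp + fn) if tp + fn else np.nan)
        sp.append(100.0 * tn / (tn + fp) if tn + fp else np.nan)
    return ca, np.array(se), np.array(sp)


def trace_of(output, fs=100.0):
    output = np.asarray(output)
    return DecisionTrace(output=output, raw=output, updates=[],
                         times=np.arange(output.size) / fs)


class TestScoreSteady:
    def test_perfect_trace(self):
        truth = np.repeat(np.arange(7), 10)
        mask = np.ones(truth.size, dtype=bool)
        counts, rep = score_steady(truth, truth, mask)
        assert rep.ca == rep.se_mean == rep.sp_mean == 100.0
        assert np.trace(counts) == truth.size

    def test_binary_toy_sensitivity_specificity(self):
        """TP=8 FN=2 TN=9 FP=1 for level walking -> SE 80%, SP 90%."""
        lw, st = int(M.LW), int(M.ST)
        truth = np.array([lw] * 10 + [st] * 10)
        pred = np.array([lw] * 8 + [st] * 2 + [st] * 9 + [lw] * 1)
        _, rep = score_steady(pred, truth, np.ones(20, dtype=bool))
        assert rep.se_per_class[lw] == pytest.approx(80.0)
        assert rep.sp_per_class[lw] == pytest.approx(90.0)
        assert rep.ca == pytest.approx(100.0 * 17 / 20)

    def test_degenerate_predictor_on_balanced_truth(self):
        truth = np.repeat(np.arange(7), 12)
        pred = np.full(truth.size, int(M.S))
        _, rep = score_steady(pred, truth, np.ones(truth.size, dtype=bool))
        assert rep.ca == pytest.approx(100.0 / 7)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="steady mask"):
            score_steady(np.zeros(5), np.zeros(5), np.zeros(5, dtype=bool))

    def test_matches_independent_tally_on_random_pairs(self):
        rng = np.random.default_rng(13)
        truth = rng.integers(0, N_MODES, size=1000)
        pred = np.where(rng.uniform(size=1000) < 0.7, truth,
                        rng.integers(0, N_MODES, size=1000))
        counts, rep = score_steady(pred, truth, np.ones(1000, dtype=bool))
        ca, se, sp = tally_metrics(truth, pred)
        assert rep.ca == pytest.approx(ca)
        np.testing.assert_allclose(rep.se_per_class, se)
        np.testing.assert_allclose(rep.sp_per_class, sp)
        # conservation: row sums equal per-class truth counts
        np.testing.assert_array_equal(counts.sum(axis=1),
                                      np.bincount(truth, minlength=N_MODES))
        assert counts.sum() == 1000


class TestScoreTransitions:
    # One LW->SA transition: cycle [0.5, 1.0), onset 1.0 s, steady to 2.0 s.
    TRANS = [Transition(0.5, 1.0, M.SA, 2.0)]

    def test_early_hold_counts_with_negative_rt(self):
        out = np.full(200, int(M.LW))
        out[70:] = int(M.SA)                        # switches 0.7 s, holds
        pa, outcomes = score_transitions(trace_of(out), self.TRANS)
        assert pa == 100.0
        assert outcomes[0].rt_ms == pytest.approx(-300.0)

    def test_flicker_does_not_claim_early_prediction(self):
        out = np.full(200, int(M.LW))
        out[60:70] = int(M.SA)                      # transient flicker
        out[120:] = int(M.SA)                       # settles after onset
        pa, outcomes = score_transitions(trace_of(out), self.TRANS)
        assert pa == 100.0
        assert outcomes[0].rt_ms == pytest.approx(+200.0)

    def test_switch_exactly_at_onset_gives_zero_rt(self):
        out = np.full(200, int(M.LW))
        out[100:] = int(M.SA)
        _, outcomes = score_transitions(trace_of(out), self.TRANS)
        assert outcomes[0].rt_ms == pytest.approx(0.0)

    def test_never_reaching_mode_not_counted(self):
        out = np.full(200, int(M.LW))
        pa, outcomes = score_transitions(trace_of(out), self.TRANS)
        assert pa == 0.0
        assert not outcomes[0].predicted and outcomes[0].rt_ms is None

    def test_no_transitions_gives_undefined_pa(self):
        pa, outcomes = score_transitions(trace_of(np.zeros(10)), [])
        assert pa is None and outcomes == []

    def test_mixed_transitions_pa(self):
        trans = [Transition(0.5, 1.0, M.SA, 1.5),
                 Transition(1.5, 2.0, M.LW, 3.0)]
        out = np.full(300, int(M.LW))
        out[80:150] = int(M.SA)                     # predicts SA early...
        out[150:] = int(M.SA)                       # ...but never returns to LW
        pa, outcomes = score_transitions(trace_of(out), trans)
        assert pa == pytest.approx(50.0)
        assert outcomes[0].predicted and not outcomes[1].predicted
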