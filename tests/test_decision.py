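"""Agreement vote, transition-legality rules, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitfusion import (DecisionConfig, decide_stream, default_rules,
                        update_latency_ms)
from gaitfusion.modes import N_MODES, LocomotionMode

M = LocomotionMode


def naive_decide(raw, config, rules):
    """O(N * agreement_n) re-scan reference implementation."""
    out = []
    current = int(config.initial_mode)
    n = config.agreement_n
    for k in range(len(raw)):
        v = int(raw[k])
        window = raw[max(0, k - n + 1): k + 1]
        if (v != current and len(window) == n and all(x == v for x in window)
                and rules.allowed[current, v]):
            current = v
        out.append(current)
    return np.array(out)


class TestRuleTable:
    def test_legal_and_illegal_pairs(self):
        rules = default_rules()
        assert rules.is_allowed(M.S, M.ST)
        assert not rules.is_allowed(M.ST, M.S)          # not symmetric
        assert not rules.is_allowed(M.SA, M.RA)
        assert not rules.is_allowed(M.LW, M.S)
        assert rules.is_allowed(M.RA, M.LW)

    def test_row_sums(self):
        rules = default_rules()
        sums = {m.name: int(rules.allowed[m].sum()) for m in M}
        assert sums == {"S": 2, "ST": 2, "LW": 6, "SA": 2, "SD": 2, "RA": 2, "RD": 2}
        assert rules.allowed.sum() == 18

    def test_diagonal_true(self):
        assert np.all(np.diag(default_rules().allowed))

    def test_json_roundtrip(self, tmp_path):
        rules = default_rules()
        rules.to_json(tmp_path / "rules.json")
        back = type(rules).from_json(tmp_path / "rules.json")
        np.testing.assert_array_equal(back.allowed, rules.allowed)


class TestDecideStream:
    def test_update_exactly_at_agreement_n(self):
        raw = np.concatenate([[int(M.ST)] * 50, [int(M.LW)] * 200])
        trace = decide_stream(raw, DecisionConfig(100, M.ST))
        # 99 agreeing samples are not enough; the 100th triggers the switch
        assert trace.output[50 + 98] == M.ST
        assert trace.output[50 + 99] == M.LW
        assert len(trace.updates) == 1

    def test_forbidden_transition_never_taken(self):
        raw = np.full(1000, int(M.LW))
        trace = decide_stream(raw, DecisionConfig(100, M.S))
        assert np.all(trace.output == int(M.S))          # S -> LW is illegal
        assert trace.updates == []

    def test_alternating_stream_never_updates(self):
        raw = np.tile([int(M.LW), int(M.SA)], 500)
        trace = decide_stream(raw, DecisionConfig(100, M.LW))
        assert np.all(trace.output == int(M.LW))

    def test_constant_stream_identity(self):
        raw = np.full(500, int(M.LW))
        trace = decide_stream(raw, DecisionConfig(100, M.LW))
        assert np.all(trace.output == int(M.LW)) and trace.updates == []

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown mode label"):
            decide_stream(np.array([0, 1, 9]), DecisionConfig(2, M.S))

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            decide_stream(np.array([]), DecisionConfig(2, M.S))

    def test_matches_naive_rescan_on_random_streams(self):
        rng = np.random.default_rng(7)
        rules = default_rules()
        for _ in range(30):
            raw = rng.integers(0, N_MODES, size=300)
            cfg = DecisionConfig(int(rng.integers(1, 8)),
                                 M(int(rng.integers(0, N_MODES))))
            trace = decide_stream(raw, cfg, rules)
            np.testing.assert_array_equal(trace.output,
                                          naive_decide(raw.tolist(), cfg, rules))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        raw=st.lists(st.integers(0, N_MODES - 1), min_size=1, max_size=300),
        n=st.integers(1, 10),
        init=st.integers(0, N_MODES - 1),
    )
    def test_legality_and_stability_properties(self, raw, n, init):
        """Every consecutive output pair is legal, and the output changes
        only when the trailing n raw labels agree on the new mode."""
        rules = default_rules()
        trace = decide_stream(np.array(raw), DecisionConfig(n, M(init)), rules)
        out = trace.output
        for k in np.flatnonzero(np.diff(out)) + 1:
            assert rules.allowed[out[k - 1], out[k]]
            assert k + 1 >= n
            assert all(r == out[k] for r in raw[k - n + 1: k + 1])


class TestUpdateLatency:
    @pytest.mark.parametrize("n,fs,expected", [(100, 2000, 50.0),
                                               (1, 2000, 0.5),
                                               (100, 1000, 100.0)])
    def test_latency_values(self, n, fs, expected):
        assert update_latency_ms(n, fs) == pytest.approx(expected)
        assert update_latency_ms(DecisionConfig(n, M.ST), fs) == pytest.approx(expected)

    def test_bad_fs_rejected(self):
        with pytest.raises(ValueError):
            update_latency_ms(100, 0)
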