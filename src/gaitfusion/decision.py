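"""Online decision layer: agreement vote plus transition-legality constraint.

The raw per-sample classifier stream is noisy; two mechanisms stabilise it.
First, a majority-vote rule: the reported mode only updates once the last
``agreement_n`` consecutive raw labels (including the current one) agree on
a mode different from the current output.  At 2000 Hz with the default
``agreement_n = 100`` this imposes a 50 ms minimum recognition delay.
Second, a content-constraint rule: an update is applied only if the
(previous mode, candidate mode) pair is legal under a 7x7 rule table that
encodes physically plausible mode sequences (sitting can only go to
standing, standing only to level walking, level walking to anything but
sitting, and stair/ramp modes only back to level walking).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .modes import MODE_NAMES, N_MODES, LocomotionMode

__all__ = [
    "TransitionRuleTable",
    "DecisionConfig",
    "DecisionTrace",
    "default_rules",
    "decide_stream",
    "update_latency_ms",
]


@dataclass(frozen=True)
class TransitionRuleTable:
    """Boolean legality matrix indexed (previous mode, candidate mode).

    The diagonal is always true (staying in a mode is legal).  The matrix
    is not symmetric: sit -> stand is legal while stand -> sit is not.
    """

    allowed: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.allowed, dtype=bool)
        if a.shape != (N_MODES, N_MODES):
            raise ValueError(f"rule table must be {N_MODES}x{N_MODES}, got {a.shape}")
        if not np.all(np.diag(a)):
            raise ValueError("self-transitions must be allowed (diagonal true)")
        object.__setattr__(self, "allowed", a)

    def is_allowed(
        self,
        previous: LocomotionMode | int | str,
        current: LocomotionMode | int | str,
    ) -> bool:
        p = LocomotionMode.from_any(previous)
        c = LocomotionMode.from_any(current)
        return bool(self.allowed[p, c])

    def __getitem__(self, key) -> bool:
        return self.is_allowed(*key)

    def to_json(self, path: str | Path) -> None:
        doc = {
            MODE_NAMES[i]: {MODE_NAMES[j]: int(self.allowed[i, j]) for j in range(N_MODES)}
            for i in range(N_MODES)
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionRuleTable":
        doc = json.loads(Path(path).read_text())
        a = np.zeros((N_MODES, N_MODES), dtype=bool)
        for pname, row in doc.items():
            p = LocomotionMode.from_any(pname)
            for cname, v in row.items():
                a[p, LocomotionMode.from_any(cname)] = bool(v)
        return cls(a)


# Legal mode successions: row = previous mode, entries = reachable modes.
_DEFAULT_RULES: dict[LocomotionMode, tuple[LocomotionMode, ...]] = {
    LocomotionMode.S: (LocomotionMode.S, LocomotionMode.ST),
    LocomotionMode.ST: (LocomotionMode.ST, LocomotionMode.LW),
    LocomotionMode.LW: (
        LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.SA,
        LocomotionMode.SD, LocomotionMode.RA, LocomotionMode.RD,
    ),
    LocomotionMode.SA: (LocomotionMode.SA, LocomotionMode.LW),
    LocomotionMode.SD: (LocomotionMode.SD, LocomotionMode.LW),
    LocomotionMode.RA: (LocomotionMode.RA, LocomotionMode.LW),
    LocomotionMode.RD: (LocomotionMode.RD, LocomotionMode.LW),
}


def default_rules() -> TransitionRuleTable:
    """The default 7x7 transition-legality table (18 allowed cells)."""
    a = np.zeros((N_MODES, N_MODES), dtype=bool)
    for prev, nexts in _DEFAULT_RULES.items():
        for nxt in nexts:
            a[prev, nxt] = True
    return TransitionRuleTable(a)


@dataclass(frozen=True)
class DecisionConfig:
    """Parameters of the online vote.

    agreement_n
        Number of consecutive identical raw labels required before the
        output may update (default 100 -> 50 ms at 2000 Hz).
    initial_mode
        Output mode before any update; conventionally the first scripted
        mode of the trial (trials start seated or standing).
    """

    agreement_n: int = 100
    initial_mode: LocomotionMode = LocomotionMode.ST

    def __post_init__(self) -> None:
        if self.agreement_n < 1:
            raise ValueError("agreement_n must be >= 1")
        object.__setattr__(self, "initial_mode", LocomotionMode.from_any(self.initial_mode))


@dataclass
class DecisionTrace:
    """Per-sample online output together with its update history."""

    output: np.ndarray                       # stabilised mode code per sample
    raw: np.ndarray                          # raw classifier labels
    updates: list[tuple[float, int, int]]    # (time_s, from_mode, to_mode)
    times: np.ndarray = field(default=None)  # sample times (s), optional

    def to_frame(self):
        import pandas as pd

        t = self.times if self.times is not None else np.arange(len(self.raw), dtype=float)
        return pd.DataFrame({"time_s": t, "raw": self.raw, "output": self.output})


def decide_stream(
    raw_labels: np.ndarray,
    config: DecisionConfig,
    rules: TransitionRuleTable | None = None,
    times: np.ndarray | None = None,
) -> DecisionTrace:
    """Stabilise a raw classifier stream with the vote + legality rules.

    At sample ``k`` the output switches to mode ``m`` iff the last
    ``agreement_n`` raw labels (inclusive of ``k``) all equal ``m``, ``m``
    differs from the current output, and the transition is legal.  The
    agreement count is a pure function of the raw-stream suffix: a blocked
    candidate gains nothing from its blocked streak.

    Raises ``ValueError`` on an empty stream or unknown label codes.
    """
    if rules is None:
        rules = default_rules()
    raw = np.asarray(raw_labels)
    if raw.size == 0:
        raise ValueError("raw label stream is empty")
    raw = raw.astype(np.int64)
    if raw.min() < 0 or raw.max() >= N_MODES:
        bad = raw[(raw < 0) | (raw >= N_MODES)][0]
        raise ValueError(f"unknown mode label in stream: {bad}")
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.shape != raw.shape:
            raise ValueError("times must align with raw_labels")

    n_req = config.agreement_n
    allowed = rules.allowed
    out = np.empty(raw.size, dtype=np.int64)
    current = int(config.initial_mode)
    updates: list[tuple[float, int, int]] = []

    run_val = raw[0]
    run_len = 0
    for k in range(raw.size):
        v = raw[k]
        if v == run_val:
            run_len += 1
        else:
            run_val = v
            run_len = 1
        if v != current and run_len >= n_req and allowed[current, v]:
            t = float(times[k]) if times is not None else float(k)
            updates.append((t, current, int(v)))
            current = int(v)
        out[k] = current

    return DecisionTrace(output=out, raw=raw, updates=updates, times=times)


def update_latency_ms(config: DecisionConfig | int, fs: float) -> float:
    """Minimum delay (ms) between a raw-stream change and an output update."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = config.agreement_n if isinstance(config, DecisionConfig) else int(config)
    return n / fs * 1000.0
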