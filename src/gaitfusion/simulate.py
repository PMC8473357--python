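"""Seedable synthetic gait trials: sEMG, segment accelerations and markers.

Real multi-channel recordings of the seven-mode locomotion protocol are not
publicly deposited, so this module generates trials with the statistical
structure the downstream analysis assumes:

* 14 sEMG channels (7 muscles x both legs) modelled as a phase-locked,
  mode-specific activation envelope multiplying a band-limited (30-300 Hz)
  unit-variance carrier, plus a small wide-band noise floor;
* 21 acceleration channels (7 placements x 3 axes) modelled as a constant
  gravity projection per segment orientation plus smooth gait-cycle-periodic
  oscillations and Gaussian sensor noise;
* anterior marker traces for heel, toe and pelvis whose heel-minus-pelvis
  coordinate peaks once per gait cycle exactly at the heel strikes
  (the coordinate-based heel-strike definition);
* a ground-truth mode label per sample and a list of heel-strike and
  mode-onset events.

The physiologically central property is the *activation lead*: at every
scripted transition the EMG envelopes begin switching to the next mode's
template ``emg_lead_ms`` before the accelerations and the ground-truth mode
onset do, emulating the fact that muscle activation precedes the mechanical
movement it drives.  Both switches are linear cross-fades over ``ramp_ms``
starting at their respective switch times, so the first envelope deviation
from the old template occurs exactly ``emg_lead_ms`` before the onset.

Each pair of consecutive steady segments is bridged by one dedicated
*transition* gait cycle: the ground-truth label switches at its midpoint
(the kinematic switch), the accelerations and the ``mode_onset`` event
switch at the heel strike ending it (the actual start of the next steady
mode, T_actual of the response-time definition), and the EMG envelopes
switch ``emg_lead_ms`` before that onset.  Quasi-static modes (sit, stand)
are simulated with nominal pseudo-cycles of the same nominal duration so
that the cycle-based segmentation applies uniformly and every mode onset
coincides with a heel-strike-like marker maximum.

The activation-magnitude contrasts between modes are design parameters of
the generator, not measured quantities; they are chosen so that modes are
separable with margins well above the default noise levels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .decision import default_rules
from .modes import TASK_SCRIPTS, LocomotionMode

__all__ = [
    "SimulationConfig",
    "Trial",
    "GaitEvent",
    "EMG_CHANNEL_NAMES",
    "ACCEL_CHANNEL_NAMES",
    "MARKER_NAMES",
    "mode_templates",
    "simulate_trial",
    "write_trial",
    "read_trial",
]

_MUSCLES = ("RF", "VL", "BF", "Sem", "TA", "MG", "LG")
EMG_CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"emg_{m}_{side}" for side in ("R", "L") for m in _MUSCLES
)

_PLACEMENTS = ("pelvis", "thigh_R", "thigh_L", "shank_R", "shank_L", "foot_R", "foot_L")
_AXES = ("x", "y", "z")
ACCEL_CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"acc_{p}_{ax}" for p in _PLACEMENTS for ax in _AXES
)

MARKER_NAMES: tuple[str, ...] = ("heel_ant", "toe_ant", "pelvis_ant")

_G = 9.81

# --- Mode templates -------------------------------------------------------
# Tonic activation level per (mode, muscle); dimensionless envelope units
# on a 0-1 scale.  Rows follow the LocomotionMode encoding.
_EMG_TONIC = np.array([
    #  RF    VL    BF    Sem   TA    MG    LG
    [0.03, 0.03, 0.03, 0.03, 0.03, 0.03, 0.03],   # S
    [0.05, 0.06, 0.04, 0.04, 0.05, 0.08, 0.07],   # ST
    [0.30, 0.35, 0.25, 0.22, 0.40, 0.45, 0.38],   # LW
    [0.75, 0.80, 0.35, 0.30, 0.55, 0.50, 0.45],   # SA
    [0.55, 0.60, 0.25, 0.20, 0.30, 0.65, 0.60],   # SD
    [0.60, 0.55, 0.55, 0.62, 0.45, 0.70, 0.40],   # RA
    [0.40, 0.32, 0.45, 0.40, 0.62, 0.35, 0.55],   # RD
])

# Raised-cosine burst riding on the tonic level (walking modes only).
_EMG_BURST_SCALE = np.array([0.0, 0.0, 0.30, 0.25, 0.28, 0.30, 0.26])
_EMG_BURST_CENTER = np.array([0.10, 0.14, 0.55, 0.60, 0.05, 0.45, 0.50])
_EMG_BURST_WIDTH = 0.35

# Segment pitch (degrees) per (mode, placement): sets the constant gravity
# projection on each accelerometer.  Sitting flips the thighs horizontal.
_ACC_PITCH_DEG = np.array([
    # pelvis thR  thL  shR  shL  ftR  ftL
    [12.0, 80.0, 80.0, 8.0, 8.0, 2.0, 2.0],       # S
    [0.0, 2.0, 2.0, 2.0, 2.0, 0.0, 0.0],          # ST
    [3.0, 8.0, 8.0, 12.0, 12.0, 6.0, 6.0],        # LW
    [7.0, 25.0, 25.0, 24.0, 24.0, 13.0, 13.0],    # SA
    [2.0, 14.0, 14.0, 30.0, 30.0, -18.0, -18.0],  # SD
    [9.0, 18.0, 18.0, 17.0, 17.0, 16.0, 16.0],    # RA
    [-5.0, 11.0, 11.0, 23.0, 23.0, -13.0, -13.0], # RD
])
_ACC_ROLL_DEG = np.array([4.0, 0.0, 1.0, 2.0, 2.0, 3.0, 1.0])  # per mode

_ACC_OSC_BASE = np.array([0.6, 1.2, 1.2, 1.8, 1.8, 2.5, 2.5])  # per placement, m/s^2
_ACC_OSC_MODE = np.array([0.0, 0.0, 1.0, 0.8, 1.15, 0.9, 1.05])  # per mode
_ACC_OSC_AXIS = np.array([1.0, 0.5, 0.8])

_ENVELOPE_FLOOR = 0.02
_STEP_AMPLITUDE_M = 0.25   # heel-minus-pelvis anterior excursion
_WALK_SPEED_MS = 1.2


def _emg_envelope_at(mode: LocomotionMode, phase: np.ndarray) -> np.ndarray:
    """Per-channel EMG activation envelope at fractional gait phase."""
    phase = np.asarray(phase, dtype=float) % 1.0
    out = np.empty((len(EMG_CHANNEL_NAMES), phase.size))
    tonic = _EMG_TONIC[mode]
    scale = _EMG_BURST_SCALE[mode]
    for side_idx, side_shift in enumerate((0.0, 0.5)):   # right, left
        for m in range(len(_MUSCLES)):
            d = (phase - (_EMG_BURST_CENTER[m] + side_shift)) % 1.0
            d = np.minimum(d, 1.0 - d)                   # wrapped distance
            burst = np.where(
                d < _EMG_BURST_WIDTH / 2,
                0.5 * (1 + np.cos(2 * np.pi * d / _EMG_BURST_WIDTH)),
                0.0,
            )
            level = tonic[m] * (1.0 if side_idx == 0 else 0.95)
            out[side_idx * 7 + m] = level + scale * burst
    return np.maximum(out, _ENVELOPE_FLOOR)


def _accel_template_at(mode: LocomotionMode, phase: np.ndarray) -> np.ndarray:
    """Per-channel clean acceleration (gravity offset + oscillation)."""
    phase = np.asarray(phase, dtype=float)
    out = np.empty((len(ACCEL_CHANNEL_NAMES), phase.size))
    for p, placement in enumerate(_PLACEMENTS):
        pitch = math.radians(_ACC_PITCH_DEG[mode, p])
        roll = math.radians(_ACC_ROLL_DEG[mode])
        offsets = (_G * math.sin(pitch), _G * math.sin(roll), _G * math.cos(pitch))
        amp = _ACC_OSC_BASE[p] * _ACC_OSC_MODE[mode]
        half = 0.5 if placement.endswith("_L") else 0.0   # left leg anti-phase
        for ax in range(3):
            psi1 = 2 * np.pi * (0.13 * p + 0.31 * ax + 0.07 * int(mode))
            psi2 = 2 * np.pi * (0.21 * p + 0.17 * ax)
            a = amp * _ACC_OSC_AXIS[ax]
            out[p * 3 + ax] = (
                offsets[ax]
                + a * np.cos(2 * np.pi * (phase + half) + psi1)
                + 0.4 * a * np.cos(4 * np.pi * (phase + half) + psi2)
            )
    return out


def mode_templates(
    mode: LocomotionMode | int | str, n_points: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-channel templates over one normalised gait cycle.

    Returns ``(emg_envelopes, accel_waveforms)`` with shapes (14, n_points)
    and (21, n_points).  EMG envelopes are smooth and nonnegative; distinct
    modes differ in at least one channel by a margin well above the default
    noise levels.
    """
    mode = LocomotionMode.from_any(mode)
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    phase = np.arange(n_points) / n_points
    return _emg_envelope_at(mode, phase), _accel_template_at(mode, phase)


# --- Configuration and trial containers ----------------------------------

@dataclass(frozen=True)
class GaitEvent:
    time_s: float
    kind: str                    # "heel_strike" | "mode_onset"
    mode: LocomotionMode


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-trial generator.

    Defaults mirror the study conditions: 2000 Hz sampling, ~1.1 s gait
    cycles with 5% jitter, and a 300 ms EMG activation lead at every
    transition (a typical anticipatory-activation interval).
    """

    task_script: tuple[LocomotionMode, ...] = TASK_SCRIPTS[2]
    fs: float = 2000.0
    cycle_duration_s: float = 1.1
    cycle_jitter_s: float = 0.055
    n_cycles_per_mode: int = 4
    emg_lead_ms: float = 300.0
    ramp_ms: float = 100.0
    emg_noise_snr: float = 20.0        # envelope scale / wide-band noise SD
    accel_noise_sd: float = 0.5        # m/s^2
    carrier: str = "bandnoise"         # "bandnoise" | "tone"
    seed: int = 0

    def __post_init__(self) -> None:
        script = tuple(LocomotionMode.from_any(m) for m in self.task_script)
        object.__setattr__(self, "task_script", script)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.cycle_duration_s <= 0:
            raise ValueError("cycle_duration_s must be positive")
        if self.cycle_jitter_s < 0:
            raise ValueError("cycle_jitter_s must be nonnegative")
        if self.n_cycles_per_mode < 1:
            raise ValueError("n_cycles_per_mode must be >= 1")
        if self.emg_lead_ms < 0:
            raise ValueError("emg_lead_ms must be nonnegative")
        if self.ramp_ms < 0:
            raise ValueError("ramp_ms must be nonnegative")
        if self.carrier not in ("bandnoise", "tone"):
            raise ValueError("carrier must be 'bandnoise' or 'tone'")
        if not script:
            raise ValueError("task_script is empty")
        rules = default_rules()
        for a, b in zip(script[:-1], script[1:]):
            if a == b:
                raise ValueError(f"script repeats mode {a.name}; segments must alternate")
            if not rules.is_allowed(a, b):
                raise ValueError(f"illegal script transition {a.name}->{b.name}")
        # The EMG switch (onset - lead) must fall inside the transition
        # cycle even at the shortest jittered duration (0.8x nominal).
        if self.emg_lead_ms / 1000.0 >= 0.8 * self.cycle_duration_s:
            raise ValueError(
                "emg_lead_ms must be shorter than one (jittered) gait cycle"
            )

    @classmethod
    def for_task(cls, task: int, **kwargs) -> "SimulationConfig":
        """Config for one of the five scripted tasks (1-5)."""
        if task not in TASK_SCRIPTS:
            raise ValueError(f"task must be in {sorted(TASK_SCRIPTS)}, got {task}")
        return cls(task_script=TASK_SCRIPTS[task], **kwargs)

    def to_dict(self) -> dict:
        return {
            "task_script": [m.name for m in self.task_script],
            "fs": self.fs,
            "cycle_duration_s": self.cycle_duration_s,
            "cycle_jitter_s": self.cycle_jitter_s,
            "n_cycles_per_mode": self.n_cycles_per_mode,
            "emg_lead_ms": self.emg_lead_ms,
            "ramp_ms": self.ramp_ms,
            "emg_noise_snr": None if math.isinf(self.emg_noise_snr) else self.emg_noise_snr,
            "accel_noise_sd": self.accel_noise_sd,
            "carrier": self.carrier,
            "seed": self.seed,
        }


@dataclass
class Trial:
    """One synchronized multi-channel recording with ground truth."""

    emg: np.ndarray                  # (14, T) mV-scale, zero-mean carrier
    accel: np.ndarray                # (21, T) m/s^2
    markers: np.ndarray              # (3, T) anterior positions (heel, toe, pelvis)
    fs: float
    truth_labels: np.ndarray         # (T,) mode codes
    truth_events: list[GaitEvent]
    config: SimulationConfig | None = None
    # Simulation diagnostics (not serialized): the clean envelopes/templates
    # actually used, for exact timing measurements in tests.
    emg_envelope: np.ndarray | None = field(default=None, repr=False)
    accel_clean: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def heel_strike_times(self) -> np.ndarray:
        return np.array([e.time_s for e in self.truth_events if e.kind == "heel_strike"])

    def mode_onsets(self) -> list[GaitEvent]:
        return [e for e in self.truth_events if e.kind == "mode_onset"]


def _band_limited_carrier(rng: np.random.Generator, n_ch: int, n: int, fs: float) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    sos = sps.butter(4, [30.0, 300.0], btype="bandpass", fs=fs, output="sos")
    car = sps.sosfiltfilt(sos, white, axis=1)
    car /= car.std(axis=1, keepdims=True)
    return car


def _tone_carrier(n_ch: int, n: int, fs: float) -> np.ndarray:
    # Deterministic in-band carriers with unit RMS: one tone per channel.
    t = np.arange(n) / fs
    freqs = 120.0 + 10.0 * np.arange(n_ch)
    phases = 0.7 * np.arange(n_ch)
    return math.sqrt(2.0) * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])


def simulate_trial(config: SimulationConfig) -> Trial:
    """Generate one trial; identical configs produce bit-identical trials."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    script = config.task_script
    ncpm = config.n_cycles_per_mode
    # ncpm steady cycles per scripted mode plus one transition cycle
    # bridging each consecutive pair of segments.
    n_cycles = ncpm * len(script) + (len(script) - 1)

    durations = rng.normal(config.cycle_duration_s, config.cycle_jitter_s, n_cycles)
    durations = np.clip(durations, 0.8 * config.cycle_duration_s, 1.2 * config.cycle_duration_s)

    pad = 0.35 * config.cycle_duration_s
    hs_times = pad + np.concatenate([[0.0], np.cumsum(durations)])   # n_cycles + 1 strikes
    total_s = hs_times[-1] + pad
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # Piecewise-linear cumulative phase; integer values at heel strikes.
    phase = np.interp(t, hs_times, np.arange(n_cycles + 1).astype(float))
    pre = t < hs_times[0]
    phase[pre] = (t[pre] - hs_times[0]) / durations[0]
    post = t > hs_times[-1]
    phase[post] = n_cycles + (t[post] - hs_times[-1]) / durations[-1]
    frac = phase % 1.0

    # Mode timelines.  The j-th transition cycle spans heel strikes
    # [idx_t, idx_t + 1] with idx_t = j*(ncpm+1) - 1; ground truth switches
    # at its midpoint, accelerations and the mode_onset event at its ending
    # heel strike, and EMG emg_lead_ms before that onset.
    onset_times = [float(hs_times[j * (ncpm + 1)]) for j in range(1, len(script))]
    label_switch_times = [
        float(0.5 * (hs_times[j * (ncpm + 1) - 1] + hs_times[j * (ncpm + 1)]))
        for j in range(1, len(script))
    ]
    lead_s = config.emg_lead_ms / 1000.0
    ramp_s = config.ramp_ms / 1000.0

    def _blend(template_at, switch_times: Sequence[float]) -> np.ndarray:
        out = template_at(script[0], frac)
        for j, sw in enumerate(switch_times, start=1):
            old, new = script[j - 1], script[j]
            i0 = int(np.searchsorted(t, sw))
            i1 = int(np.searchsorted(t, sw + ramp_s)) if ramp_s > 0 else i0
            if i1 > i0:
                w = (t[i0:i1] - sw) / ramp_s
                out[:, i0:i1] = (
                    (1 - w) * template_at(old, frac[i0:i1])
                    + w * template_at(new, frac[i0:i1])
                )
            out[:, i1:] = template_at(new, frac[i1:])
        return out

    emg_switches = [o - lead_s for o in onset_times]
    for j, sw in enumerate(emg_switches, start=1):
        t_cycle_start = float(hs_times[j * (ncpm + 1) - 1])
        if sw < t_cycle_start:
            raise ValueError("emg_lead_ms reaches back before the transition cycle")

    envelope = _blend(_emg_envelope_at, emg_switches)
    accel_clean = _blend(_accel_template_at, onset_times)

    if config.carrier == "bandnoise":
        carrier = _band_limited_carrier(rng, len(EMG_CHANNEL_NAMES), n, fs)
    else:
        carrier = _tone_carrier(len(EMG_CHANNEL_NAMES), n, fs)
    wb_sd = 0.0 if math.isinf(config.emg_noise_snr) else 1.0 / config.emg_noise_snr
    emg = envelope * carrier
    if wb_sd > 0:
        emg = emg + wb_sd * rng.standard_normal(emg.shape)

    accel = accel_clean.copy()
    if config.accel_noise_sd > 0:
        accel = accel + config.accel_noise_sd * rng.standard_normal(accel.shape)

    # Truth labels switch at the transition-cycle midpoints.
    labels = np.full(n, int(script[0]), dtype=np.int64)
    for j, sw in enumerate(label_switch_times, start=1):
        labels[t >= sw] = int(script[j])

    # Markers: pelvis advances at walking speed during ambulatory modes.
    walking = np.isin(labels, [int(LocomotionMode.LW), int(LocomotionMode.SA),
                               int(LocomotionMode.SD), int(LocomotionMode.RA),
                               int(LocomotionMode.RD)])
    v = np.where(walking, _WALK_SPEED_MS, 0.02)
    pelvis = np.cumsum(v) / fs
    heel = pelvis + _STEP_AMPLITUDE_M * np.cos(2 * np.pi * phase)
    toe = pelvis + _STEP_AMPLITUDE_M * np.cos(2 * np.pi * phase - 2.2) - 0.05
    markers = np.vstack([heel, toe, pelvis])

    events: list[GaitEvent] = []
    for hs in hs_times:
        idx = min(n - 1, int(round(hs * fs)))
        events.append(GaitEvent(float(hs), "heel_strike", LocomotionMode(int(labels[idx]))))
    for j, onset in enumerate(onset_times, start=1):
        events.append(GaitEvent(float(onset), "mode_onset", script[j]))
    events.sort(key=lambda e: (e.time_s, e.kind))

    return Trial(
        emg=emg, accel=accel, markers=markers, fs=fs,
        truth_labels=labels, truth_events=events, config=config,
        emg_envelope=envelope, accel_clean=accel_clean,
    )


# --- Plain-text persistence ----------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write a trial as TSV (one column per channel) + JSON sidecar."""
    path = Path(path)
    names = list(EMG_CHANNEL_NAMES) + list(ACCEL_CHANNEL_NAMES) + list(MARKER_NAMES)
    data = np.vstack([trial.emg, trial.accel, trial.markers]).T
    np.savetxt(path, data, fmt="%.12g", delimiter="\t",
               header="\t".join(names), comments="")

    # Labels stored run-length encoded: [start_sample, mode_code] pairs.
    lab = trial.truth_labels
    changes = np.flatnonzero(np.diff(lab)) + 1
    rle = [[0, int(lab[0])]] + [[int(i), int(lab[i])] for i in changes]
    doc = {
        "fs": trial.fs,
        "n_samples": int(trial.n_samples),
        "channels": {
            "emg": list(EMG_CHANNEL_NAMES),
            "accel": list(ACCEL_CHANNEL_NAMES),
            "markers": list(MARKER_NAMES),
        },
        "events": [[e.time_s, e.kind, e.mode.name] for e in trial.truth_events],
        "labels_rle": rle,
        "config": trial.config.to_dict() if trial.config is not None else None,
    }
    _sidecar_path(path).write_text(json.dumps(doc, indent=1))


def read_trial(path: str | Path) -> Trial:
    """Read a trial written by :func:`write_trial`; validates the schema."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    try:
        doc = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("fs", "n_samples", "channels", "events", "labels_rle"):
        if key not in doc:
            raise ValueError(f"sidecar missing required key {key!r}")
    ch = doc["channels"]
    for group, expected in (("emg", EMG_CHANNEL_NAMES),
                            ("accel", ACCEL_CHANNEL_NAMES),
                            ("markers", MARKER_NAMES)):
        if group not in ch:
            raise ValueError(f"sidecar channels missing group {group!r}")
        if len(ch[group]) != len(expected):
            raise ValueError(
                f"channel-count mismatch for {group}: expected "
                f"{len(expected)}, sidecar lists {len(ch[group])}"
            )

    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    expected_cols = ch["emg"] + ch["accel"] + ch["markers"]
    if header != expected_cols:
        raise ValueError("TSV header does not match sidecar channel names")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape != (doc["n_samples"], len(expected_cols)):
        raise ValueError(
            f"data shape {data.shape} does not match sidecar "
            f"({doc['n_samples']} samples x {len(expected_cols)} channels)"
        )
    n_emg, n_acc = len(ch["emg"]), len(ch["accel"])
    emg = data[:, :n_emg].T
    accel = data[:, n_emg:n_emg + n_acc].T
    markers = data[:, n_emg + n_acc:].T

    labels = np.empty(doc["n_samples"], dtype=np.int64)
    rle = doc["labels_rle"]
    for k, (start, code) in enumerate(rle):
        end = rle[k + 1][0] if k + 1 < len(rle) else doc["n_samples"]
        labels[start:end] = code
    events = [
        GaitEvent(float(ts), kind, LocomotionMode.from_any(mode))
        for ts, kind, mode in doc["events"]
    ]
    cfg = None
    if doc.get("config"):
        c = dict(doc["config"])
        c["task_script"] = tuple(LocomotionMode.from_any(m) for m in c["task_script"])
        if c.get("emg_noise_snr") is None:
            c["emg_noise_snr"] = math.inf
        cfg = SimulationConfig(**c)
    return Trial(emg=emg, accel=accel, markers=markers, fs=float(doc["fs"]),
                 truth_labels=labels, truth_events=events, config=cfg)
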