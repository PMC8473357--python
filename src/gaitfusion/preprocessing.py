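"""Zero-lag Butterworth filtering of raw EMG and acceleration channels.

EMG is band-passed 30-300 Hz (total effective order 4) to isolate the
myoelectric carrier; accelerations are low-passed at 25 Hz (total order 6)
to keep segment kinematics and reject vibration.  "Order" here counts the
*combined* magnitude response of a forward-backward (zero-phase) pass, the
convention of the gait literature: a total order of 4 is achieved by a
2nd-order design applied forward and backward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = ["FilterSpec", "zero_lag_filter", "preprocess_trial",
           "EMG_FILTER", "ACCEL_FILTER"]


@dataclass(frozen=True)
class FilterSpec:
    """A zero-lag Butterworth filter.

    ``order`` is the total effective order; it must be even, since half of
    it is realised in each direction of the forward-backward pass.
    """

    kind: str                       # "bandpass" | "lowpass"
    order: int
    band_hz: tuple[float, ...]      # one corner (lowpass) or two (bandpass)
    fs: float

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"kind must be 'bandpass' or 'lowpass', got {self.kind!r}")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be positive and even")
        band = tuple(float(b) for b in self.band_hz)
        object.__setattr__(self, "band_hz", band)
        n_corners = 2 if self.kind == "bandpass" else 1
        if len(band) != n_corners:
            raise ValueError(f"{self.kind} needs {n_corners} corner(s), got {len(band)}")
        nyq = self.fs / 2.0
        if any(not 0 < b < nyq for b in band):
            raise ValueError(f"corners must lie strictly inside (0, {nyq}) Hz")
        if n_corners == 2 and band[0] >= band[1]:
            raise ValueError("bandpass corners must be increasing")

    def design_sos(self) -> np.ndarray:
        """Second-order sections of the per-pass (order/2) design."""
        wn = self.band_hz if self.kind == "bandpass" else self.band_hz[0]
        return sps.butter(self.order // 2, wn, btype=self.kind, fs=self.fs,
                          output="sos")

    def padlen(self) -> int:
        # Reflective padding of 3x the filter's impressionable length.
        sos = self.design_sos()
        return 3 * (2 * sos.shape[0] + 1)


#: Study defaults: EMG 30-300 Hz order 4; acceleration 25 Hz order 6.
EMG_FILTER = FilterSpec("bandpass", 4, (30.0, 300.0), 2000.0)
ACCEL_FILTER = FilterSpec("lowpass", 6, (25.0,), 2000.0)


def zero_lag_filter(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth filtering; output length equals input.

    Raises ``ValueError`` if the signal is shorter than the filter warm-up
    (the reflective pad length).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    pad = spec.padlen()
    if n <= pad:
        raise ValueError(f"signal length {n} must exceed filter warm-up {pad}")
    return sps.sosfiltfilt(spec.design_sos(), x, axis=-1, padtype="even", padlen=pad)


def preprocess_trial(trial, emg_spec: FilterSpec | None = None,
                     accel_spec: FilterSpec | None = None):
    """Return a copy of a trial with EMG band-passed and accel low-passed.

    Markers, labels and events are untouched; channel counts preserved.
    """
    if trial.emg.size == 0 or trial.accel.size == 0:
        raise ValueError("trial has empty channels")
    emg_spec = emg_spec or replace(EMG_FILTER, fs=trial.fs)
    accel_spec = accel_spec or replace(ACCEL_FILTER, fs=trial.fs)
    for spec in (emg_spec, accel_spec):
        if spec.fs != trial.fs:
            raise ValueError(f"filter fs {spec.fs} != trial fs {trial.fs}")
    from dataclasses import replace as _dc_replace

    return _dc_replace(
        trial,
        emg=zero_lag_filter(trial.emg, emg_spec),
        accel=zero_lag_filter(trial.accel, accel_spec),
    )
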