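"""Sliding-window RMS features and the fused 35-element feature vector.

At every sample instant the root mean square of each preprocessed channel
over the trailing window is computed, min-max normalised with bounds
learned on training data, and assembled into the fused vector

    X_i = {T_e1 ... T_e14, T_a1 ... T_a21}

(14 EMG channels followed by the 7 placements x 3 axes of acceleration;
35 values in total).  Windows are causal — anchored at their *ending*
sample — so the decision at time t uses only samples up to t; this is what
makes measured response times meaningful for an online system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import ACCEL_CHANNEL_NAMES, EMG_CHANNEL_NAMES, Trial

__all__ = [
    "FeatureMatrix",
    "sliding_rms",
    "fit_norm_bounds",
    "apply_norm",
    "build_features",
    "modality_columns",
]

CHANNEL_ORDER: tuple[str, ...] = tuple(EMG_CHANNEL_NAMES) + tuple(ACCEL_CHANNEL_NAMES)
N_FEATURES = len(CHANNEL_ORDER)
_CLIP_LO, _CLIP_HI = -0.5, 1.5


def sliding_rms(x: np.ndarray, window_samples: int, step: int = 1) -> np.ndarray:
    """Causal sliding-window RMS.

    ``out[k]`` is the RMS of the window *ending* at sample
    ``k*step + window_samples - 1``; the output has
    ``floor((T - window)/step) + 1`` values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sliding_rms expects a 1-D signal")
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_samples > x.size:
        raise ValueError(
            f"window ({window_samples}) exceeds signal length ({x.size})"
        )
    # Direct convolution: each output depends on exactly its own window,
    # keeping the operator strictly causal (no FFT cross-talk).
    kernel = np.full(window_samples, 1.0 / window_samples)
    ms = np.convolve(x * x, kernel, mode="valid")
    return np.sqrt(np.maximum(ms[::step], 0.0))


def fit_norm_bounds(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (min, max) learned on training data.

    A constant column (max == min) is flagged with a warning; such columns
    normalise to zero.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    degenerate = np.flatnonzero(hi <= lo)
    if degenerate.size:
        warnings.warn(
            f"constant feature column(s) {degenerate.tolist()}: normalised to 0",
            stacklevel=2,
        )
    return lo, hi


def apply_norm(X: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """(x - min)/(max - min), with out-of-sample values clipped to [-0.5, 1.5]."""
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != lo.size or lo.size != hi.size:
        raise ValueError(
            f"column count mismatch: X has {X.shape[1]}, bounds have {lo.size}"
        )
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    Z = (X - lo) / safe
    Z[:, span <= 0] = 0.0
    return np.clip(Z, _CLIP_LO, _CLIP_HI)


@dataclass
class FeatureMatrix:
    """Per-instant fused RMS features with aligned labels and times."""

    X: np.ndarray                     # (N, 35) raw or normalised RMS
    y: np.ndarray                     # (N,) mode labels at window end
    t: np.ndarray                     # (N,) window-end times (s)
    window_ms: float
    channel_names: tuple[str, ...] = CHANNEL_ORDER
    norm_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def subset(self, columns: np.ndarray) -> "FeatureMatrix":
        cols = np.asarray(columns)
        nb = None
        if self.norm_bounds is not None:
            nb = (self.norm_bounds[0][cols], self.norm_bounds[1][cols])
        return FeatureMatrix(
            X=self.X[:, cols], y=self.y, t=self.t, window_ms=self.window_ms,
            channel_names=tuple(np.asarray(self.channel_names)[cols]),
            norm_bounds=nb,
        )


def modality_columns(modality: str) -> np.ndarray:
    """Column indices for 'emg' (14), 'accel' (21) or 'fusion' (35)."""
    n_emg = len(EMG_CHANNEL_NAMES)
    if modality == "emg":
        return np.arange(n_emg)
    if modality == "accel":
        return np.arange(n_emg, N_FEATURES)
    if modality == "fusion":
        return np.arange(N_FEATURES)
    raise ValueError(f"unknown modality {modality!r}")


def build_features(trial: Trial, window_ms: float) -> FeatureMatrix:
    """Causal sliding-RMS features for a (preprocessed) trial.

    One row per sample instant from the first full window onward, columns
    ordered EMG 1-14 then accel 1-21; each row's label is the ground-truth
    mode at the window's ending sample.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    w = int(round(window_ms / 1000.0 * trial.fs))
    if w < 1:
        raise ValueError(f"window of {window_ms} ms is shorter than one sample")
    channels = np.vstack([trial.emg, trial.accel])
    X = np.empty((channels.shape[1] - w + 1, channels.shape[0]))
    for c in range(channels.shape[0]):
        X[:, c] = sliding_rms(channels[c], w)
    ends = np.arange(w - 1, channels.shape[1])
    return FeatureMatrix(
        X=X,
        y=trial.truth_labels[ends].copy(),
        t=ends / trial.fs,
        window_ms=float(window_ms),
    )
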