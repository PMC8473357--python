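"""Heel-strike detection and gait-cycle segmentation.

Heel strikes are found with the coordinate-based method: local maxima of
the heel-minus-pelvis anterior coordinate mark initial foot-ground contact.
Cycles are the half-open intervals ``[HS_i, HS_{i+1})`` between consecutive
ipsilateral strikes; a cycle containing a mode switch is a gait transition,
labelled with the mode reached at its end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .modes import LocomotionMode

__all__ = ["GaitCycle", "detect_heel_strikes", "segment_cycles",
           "steady_sample_mask", "transitions_from_cycles", "Transition"]


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle ``[start_s, end_s)``.

    ``mode`` is the single mode spanning the cycle, or ``None`` for a
    transition cycle, in which case ``next_mode`` is the mode at cycle end.
    """

    start_s: float
    end_s: float
    mode: LocomotionMode | None
    next_mode: LocomotionMode | None = None

    @property
    def is_transition(self) -> bool:
        return self.mode is None


def detect_heel_strikes(
    heel_anterior: np.ndarray,
    pelvis_anterior: np.ndarray,
    fs: float,
    prominence_frac: float = 0.25,
    min_separation_s: float = 0.4,
) -> np.ndarray:
    """Times (s) of local maxima of the heel-minus-pelvis coordinate.

    Peaks must exceed a prominence of ``prominence_frac`` times the signal
    range and be separated by ``min_separation_s``.  Constant input yields
    an empty array (no gait, not an error).
    """
    heel = np.asarray(heel_anterior, dtype=float)
    pelvis = np.asarray(pelvis_anterior, dtype=float)
    if heel.shape != pelvis.shape:
        raise ValueError("heel and pelvis traces must have equal length")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rel = heel - pelvis
    rng = float(rel.max() - rel.min())
    if rng < 1e-12:
        return np.array([])
    idx, _ = sps.find_peaks(
        rel,
        prominence=prominence_frac * rng,
        distance=max(1, int(round(min_separation_s * fs))),
    )
    return idx / fs


def segment_cycles(
    event_times_s: np.ndarray,
    labels: np.ndarray,
    fs: float,
) -> list[GaitCycle]:
    """Partition [first HS, last HS) into labelled gait cycles.

    ``labels`` is the per-sample mode track.  With the half-open cycle
    convention a switch exactly at a heel strike leaves the preceding cycle
    steady; fewer than two events yield an empty list.
    """
    times = np.sort(np.asarray(event_times_s, dtype=float))
    labels = np.asarray(labels)
    if times.size < 2:
        return []
    cycles: list[GaitCycle] = []
    for t0, t1 in zip(times[:-1], times[1:]):
        i0 = int(round(t0 * fs))
        i1 = int(round(t1 * fs))
        i1 = min(i1, labels.size)
        seg = labels[i0:i1]
        if seg.size == 0:
            continue
        modes = np.unique(seg)
        if modes.size == 1:
            cycles.append(GaitCycle(t0, t1, LocomotionMode(int(modes[0]))))
        else:
            cycles.append(GaitCycle(t0, t1, None,
                                    next_mode=LocomotionMode(int(seg[-1]))))
    return cycles


def steady_sample_mask(cycles: list[GaitCycle], n_samples: int, fs: float) -> np.ndarray:
    """Boolean mask of samples lying inside steady (non-transition) cycles."""
    mask = np.zeros(n_samples, dtype=bool)
    for c in cycles:
        if not c.is_transition:
            i0 = max(0, int(round(c.start_s * fs)))
            i1 = min(n_samples, int(round(c.end_s * fs)))
            mask[i0:i1] = True
    return mask


@dataclass(frozen=True)
class Transition:
    """A gait transition: the cycle during which the mode switches.

    ``onset_s`` is the actual start of the next steady mode (the heel
    strike ending the transition cycle); ``steady_end_s`` bounds the
    following steady segment (used when scoring late recognitions).
    """

    cycle_start_s: float
    onset_s: float
    next_mode: LocomotionMode
    steady_end_s: float


def transitions_from_cycles(cycles: list[GaitCycle]) -> list[Transition]:
    """Extract transitions with their following steady-segment bounds."""
    out: list[Transition] = []
    for k, c in enumerate(cycles):
        if not c.is_transition:
            continue
        end = c.end_s
        for nxt in cycles[k + 1:]:
            if nxt.is_transition:
                break
            end = nxt.end_s
        out.append(Transition(c.start_s, c.end_s, c.next_mode, end))
    return out
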