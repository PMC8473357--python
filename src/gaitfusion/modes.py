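"""Locomotion modes and the scripted daily-living tasks.

Seven activities are distinguished: sit (S), stand (ST), level walking (LW),
stair ascent (SA), stair descent (SD), ramp ascent (RA) and ramp descent
(RD).  The integer codes are stable and used everywhere a compact label
track is needed (truth labels, classifier outputs, confusion matrices).
"""

from __future__ import annotations

from enum import IntEnum


class LocomotionMode(IntEnum):
    """The seven locomotion activities, with a stable 0-6 encoding."""

    S = 0    # sit
    ST = 1   # stand
    LW = 2   # level walk
    SA = 3   # stair ascent
    SD = 4   # stair descent
    RA = 5   # ramp ascent
    RD = 6   # ramp descent

    @classmethod
    def from_any(cls, value: "LocomotionMode | int | str") -> "LocomotionMode":
        """Coerce an int code, name string or mode into a LocomotionMode."""
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.upper()]
            except KeyError:
                raise ValueError(f"unknown locomotion mode name: {value!r}") from None
        try:
            return cls(int(value))
        except (ValueError, TypeError):
            raise ValueError(f"unknown locomotion mode code: {value!r}") from None


MODE_NAMES: tuple[str, ...] = tuple(m.name for m in LocomotionMode)
N_MODES: int = len(LocomotionMode)

#: The five scripted transition tasks, keyed 1-5: each is the ordered list of
#: steady modes a participant moves through (e.g. task 2 is
#: stand -> level walk -> stair ascent -> level walk -> stand).
TASK_SCRIPTS: dict[int, tuple[LocomotionMode, ...]] = {
    1: (LocomotionMode.S, LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.ST),
    2: (LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.SA,
        LocomotionMode.LW, LocomotionMode.ST),
    3: (LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.SD,
        LocomotionMode.LW, LocomotionMode.ST),
    4: (LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.RA,
        LocomotionMode.LW, LocomotionMode.ST),
    5: (LocomotionMode.ST, LocomotionMode.LW, LocomotionMode.RD,
        LocomotionMode.LW, LocomotionMode.ST),
}
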