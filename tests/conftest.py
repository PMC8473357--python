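import numpy as np
import pytest

from gaitfusion import SimulationConfig, simulate_trial
from gaitfusion.modes import LocomotionMode


@pytest.fixture(scope="session")
def trial_small():
    """Task 2 (stand-walk-stairs-walk-stand) trial at default noise, 2 steady
    cycles per mode: small enough for unit tests, rich enough to contain all
    four transitions."""
    cfg = SimulationConfig.for_task(2, n_cycles_per_mode=2, seed=3)
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def trial_tiny():
    """A minimal stand->walk trial used for IO and feature-shape tests."""
    cfg = SimulationConfig(
        task_script=(LocomotionMode.ST, LocomotionMode.LW),
        n_cycles_per_mode=2, seed=7,
    )
    return simulate_trial(cfg)


def make_flat_trial(emg_value=0.0, accel_value=0.0, n=6000, fs=2000.0,
                    emg_signal=None, accel_signal=None):
    """Construct a Trial with hand-set channel content (no simulation)."""
    from gaitfusion.simulate import Trial

    emg = np.full((14, n), float(emg_value))
    accel = np.full((21, n), float(accel_value))
    if emg_signal is not None:
        emg[:] = emg_signal
    if accel_signal is not None:
        accel[:] = accel_signal
    return Trial(
        emg=emg, accel=accel, markers=np.zeros((3, n)), fs=fs,
        truth_labels=np.zeros(n, dtype=np.int64), truth_events=[],
    )
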