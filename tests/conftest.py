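import numpy as np
import pytest

from adaptivepcr import SimulationConfig, simulate_run
from adaptivepcr.adaptive_control import (
    AdaptiveController,
    ControlParams,
    FluorescenceTrace,
)


def make_heating_trace(
    s_scale: float,
    t_mid: float = 12.0,
    duration: float = 25.0,
    hz: float = 30.0,
    gain: float = 1.0,
    offset: float = 0.0,
    baseline: float = 20.0,
    span: float = 100.0,
):
    """Analytic single-heating-phase traces: a logistic melt transition on the
    yellow channel (time scale ``s_scale`` seconds), flat orange."""
    t = np.arange(0.0, duration, 1.0 / hz)
    yellow = (baseline + span / (1.0 + np.exp(-(t - t_mid) / s_scale))) * gain + offset
    orange = (np.full_like(t, 50.0)) * gain + offset
    return t, yellow, orange


def run_single_melt_phase(t, yellow, orange, params: ControlParams | None = None):
    """Drive a controller through one heating phase; return it after the
    melt switch (or after the data runs out)."""
    ctrl = AdaptiveController(params or ControlParams(), n_cycles=1)
    for i in range(t.size):
        ctrl.update(float(t[i]), {"yellow": float(yellow[i]), "orange": float(orange[i])})
        if ctrl.switch_points:
            break
    return ctrl


@pytest.fixture(scope="session")
def noiseless_run3():
    """Short noiseless closed-loop run shared by structural tests."""
    return simulate_run(SimulationConfig(n_cycles=3, seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def noiseless_run40():
    """Full-length noiseless closed-loop run (the stability benchmark)."""
    return simulate_run(SimulationConfig(n_cycles=40, seed=0, noise_sd=0.0))
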