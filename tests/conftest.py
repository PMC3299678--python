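import numpy as np
import pytest

from hfcell.model import ModelParameters, SolverSettings
from hfcell.io import load_snapshot


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def control_state():
    """Packaged 1-Hz steady state of the baseline model with control I_NaL."""
    return load_snapshot("control_1hz")


@pytest.fixture(scope="session")
def hf_state():
    """Packaged 1-Hz steady state of the basic HF model."""
    return load_snapshot("hf_1hz")


@pytest.fixture(scope="session")
def rested_state(params):
    """Unstimulated near-equilibrium reached by a long quiescent settle."""
    from hfcell.model import default_initial_state, integrate
    return integrate(default_initial_state(), params, [], 60000.0,
                     record=False).final_state


@pytest.fixture(scope="session")
def control_beat(params, control_state, settings):
    """One recorded steady-state beat of the control model at 1 Hz."""
    from hfcell.protocols import _one_beat
    return _one_beat(control_state, params, 1000.0, settings, record=True,
                     output_dt=0.1)
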