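import numpy as np
import pytest

from cardiofit import ParameterVector, TNNPModel, pace
from cardiofit.fixtures import generate_target


@pytest.fixture(scope="session")
def model():
    return TNNPModel()


@pytest.fixture(scope="session")
def control():
    return ParameterVector.control()


@pytest.fixture(scope="session")
def paced_control(model, control):
    """Control run: 3 s pre-pacing + the fourth beat, CL 1000 ms."""
    return pace(model, control, duration=4000.0, cycle_length=1000.0)


@pytest.fixture(scope="session")
def paced_control_fine(model, control):
    """Same protocol sampled at 0.1 ms (for clamp-onset resolution checks)."""
    return pace(model, control, duration=4000.0, cycle_length=1000.0,
                sample_dt=0.1)


@pytest.fixture(scope="session")
def self_fit_target():
    """Noiseless target generated from the control parameters with R_m at the
    three self-fit voltage points."""
    return generate_target(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
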