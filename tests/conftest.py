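import numpy as np
import pytest

from perclock.core_model import VariantSpec
from perclock.simulate import SolverSettings
from perclock.analysis import run_single


@pytest.fixture(scope="session")
def freerun_traj():
    """Default-parameter free run, long enough for the standard 80-120 h window."""
    return run_single(settings=SolverSettings(t_end=150.0))


@pytest.fixture(scope="session")
def freerun_period(freerun_traj):
    from perclock.analysis import estimate_period

    return estimate_period(freerun_traj, "osc.M").period


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(17)
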