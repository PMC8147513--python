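import numpy as np
import pytest

from dbstune import SessionConfig, profile_ar1, run_session
from dbstune.kernels import KernelParams


@pytest.fixture(scope="session")
def ar1():
    return profile_ar1()


@pytest.fixture(scope="session")
def freq_grid():
    """The 10–155 Hz, 5 Hz candidate grid of the profile-1 patient."""
    return np.arange(10.0, 160.0, 5.0)


@pytest.fixture(scope="session")
def ar1_session(ar1):
    """One complete visit-2 session (4 seeds + 8 iterations) on profile 1."""
    config = SessionConfig(ceiling=155.0, rng_seed=0)
    return run_session(ar1, config)


@pytest.fixture
def default_kernel():
    return KernelParams(nu=1.5, ell=30.0, signal_var=1.0, noise_var=0.0)
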