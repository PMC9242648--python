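import numpy as np
import pytest

from hfskit import MotorParams, TrapConstants


@pytest.fixture(scope="session")
def consts():
    return TrapConstants()


@pytest.fixture(scope="session")
def wt_params():
    """Wild-type-like motor: k0 = 147/s, delta = 1.04 nm, step 4.3 nm."""
    return MotorParams(k0=147.0, delta=1.04, kcat=5.0, step_d=4.3, label="WT")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
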