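import numpy as np
import pytest

from drvoss import LEARNING_SET, CovariateProfile, Regimen


@pytest.fixture(scope="session")
def pop():
    return LEARNING_SET


@pytest.fixture(scope="session")
def ref_cov():
    return CovariateProfile(female=0, cyp3a5_flag=0, slco3a1_flag=0)


@pytest.fixture(scope="session")
def reg800():
    return Regimen(800.0, 24.0)


@pytest.fixture(scope="session")
def reg600():
    return Regimen(600.0, 12.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
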