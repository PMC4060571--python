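import numpy as np
import pytest

from eaafes import SOPDTModel
from eaafes.data import reference_calibrations, reference_models


@pytest.fixture(scope="session")
def subject_b_cal():
    return reference_calibrations()["B"]


@pytest.fixture(scope="session")
def reference_model():
    """The worked-example plant: K=11.22, omega_n=20.5, zeta=1, tau=0.05."""
    return reference_models()["eq12"]


@pytest.fixture(scope="session")
def model_b() -> SOPDTModel:
    return reference_models()["B"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
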