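import numpy as np
import pytest

from rdcorr.acquisition import generate_scheme
from rdcorr.forward_model import Component
from rdcorr.inversion import InversionConfig


@pytest.fixture(scope="session")
def small_scheme():
    """200-point pseudo-random scheme shared by fast tests."""
    return generate_scheme(200, seed=42)


@pytest.fixture(scope="session")
def medium_scheme():
    return generate_scheme(1000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_component():
    return Component(1.0, R1=2.0, R2=30.0, Diso=3e-10, Ddelta=0.4, theta=0.9, phi=2.0)


@pytest.fixture(scope="session")
def fast_inversion_config():
    """Cheap search schedule for unit tests that only need plausibility."""
    return InversionConfig(n_candidates=80, n_prolif=5, n_mutate=5, max_components=20)
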