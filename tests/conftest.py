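import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bamdyn.geometry import ComplexSelection
from bamdyn.synthetic_data import ToySpec, make_toy_complex

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def selection() -> ComplexSelection:
    return ComplexSelection()


@pytest.fixture
def toy_model():
    return make_toy_complex(ToySpec())


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
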