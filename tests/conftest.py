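import numpy as np
import pytest

from ogive.model import ItemParameters, ResponseMatrix, TraitVector
from ogive.synthetic import GeneratorSpec, simulate_responses


@pytest.fixture(scope="session")
def small_dataset():
    """A 500-person, 20-item synthetic data set with known truth."""
    return simulate_responses(GeneratorSpec(n=500, k=20, seed=7))


@pytest.fixture
def tiny_y():
    """The fixed 3-person, 2-item instance used for exact-posterior checks."""
    return ResponseMatrix([[1, 0], [0, 1], [1, 1]])


@pytest.fixture
def toy_items():
    return ItemParameters(alpha=np.array([1.0, 0.8]), beta=np.array([0.2, -0.3]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
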