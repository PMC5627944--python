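import numpy as np
import pytest

from synaptogen import datasets
from synaptogen.dynamics import RunParams


@pytest.fixture(scope="session")
def a1_spec():
    return datasets.get_spec("A1")


@pytest.fixture(scope="session")
def c3_spec():
    return datasets.get_spec("C3")


@pytest.fixture(scope="session")
def tiny_spec():
    """Small disjoint-prototype environment for fast structural tests."""
    return datasets.DatasetSpec(
        name="tiny",
        n_inputs=40,
        n_categories=4,
        lines_per_prototype=10,
        on_noise=3,
        off_noise=3,
        category_probs=(0.1, 0.2, 0.3, 0.4),
        block_size=20,
    )


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def base_params():
    return RunParams(epsilon=0.001, gamma=0.001)
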