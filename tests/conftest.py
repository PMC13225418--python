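import warnings

import numpy as np
import pytest

import stesh
from stesh.synthetic import SyntheticSpec

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_spec():
    """A small but nontrivial synthetic condition used across unit tests."""
    return SyntheticSpec(rows=10, cols=10, n_genes=60, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return stesh.make_dataset(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
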