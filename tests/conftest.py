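import numpy as np
import pytest

from diashrink.generative import ModelParams, simulate_arrays
from diashrink.testing import blocks_from_array


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def null_dataset(default_params):
    """One default-parameter null dataset: (x array, latents)."""
    return simulate_arrays(default_params, seed=1234)


@pytest.fixture(scope="session")
def null_blocks(null_dataset):
    x, _ = null_dataset
    return blocks_from_array(x)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
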