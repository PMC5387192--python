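import numpy as np
import pytest

from epitrend.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by unit tests."""
    return generate_dataset(SyntheticConfig(n_genes=300, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
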