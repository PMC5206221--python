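import numpy as np
import pytest

import sludgeqspr as sq


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset shared across read-only tests."""
    return sq.generate_dataset(sq.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_dataset():
    cfg = sq.GeneratorConfig(
        compound_noise_sd=0.0, replicate_spread_target=0.0, nonlinearity_amplitude=0.0
    )
    return sq.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
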