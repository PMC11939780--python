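import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight small synthetic image/mask pairs shared across tests."""
    from dfdrnet.data_synth import SynthConfig, generate_dataset

    return generate_dataset(SynthConfig(image_size=32, seed=99), 8)
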