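import numpy as np
import pytest

from lesionpipe.synthetic import GenConfig, generate_dataset, generate_sample


@pytest.fixture(scope="session")
def gen_config():
    return GenConfig()


@pytest.fixture(scope="session")
def phantom_melanoma(gen_config):
    return generate_sample(gen_config, "melanoma", 7)


@pytest.fixture(scope="session")
def phantom_batch(gen_config):
    """Small stratified batch shared across tests: 4 per class, seed 0."""
    samples, manifest = generate_dataset(gen_config, 4, 0)
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
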