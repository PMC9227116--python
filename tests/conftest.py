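import numpy as np
import pytest

from wasppnet.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects x 4 samples, enough for protocol-level tests."""
    return generate_dataset(GeneratorConfig(
        n_subjects=3, samples_per_subject=4, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
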