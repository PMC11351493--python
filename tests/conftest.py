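import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_samples():
    """A small deterministic synthetic study shared across tests."""
    from lesiondet.syndata import generate_study, tiny_registry

    return generate_study(tiny_registry(), image_size=64, seed=7)
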