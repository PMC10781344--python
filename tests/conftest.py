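import numpy as np
import pytest

from midseg.synthdata import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small deterministic synthetic dataset shared across tests."""
    return generate(SynthConfig(n_images=6, image_size=(96, 96), seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
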