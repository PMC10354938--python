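import numpy as np
import pytest

from axunet import nn
from axunet.synthdata import SynthConfig, gen_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(autouse=True)
def _seeded_init():
    """Deterministic parameter initialization for every test."""
    nn.seed_all(0)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight deterministic 64x64 synthetic lesion samples."""
    cfg = SynthConfig(image_size=64, seed=7)
    return [gen_sample(cfg, i) for i in range(8)]
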