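import numpy as np
import pytest

from stripmamba.synth import SynthConfig, gen_sample


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_samples():
    """Ten 64x64 synthetic pairs shared across tests."""
    cfg = SynthConfig(image_size=64, seed=7)
    return [gen_sample(cfg, i) for i in range(10)]
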