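import numpy as np
import pytest

from iwnet.phantoms import PhantomConfig, generate_phantom, synthetic_cohort


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """Small, fast phantom configuration used across the suite."""
    return PhantomConfig(shape=(32, 32, 32), radius_range_voxels=(3.0, 7.0),
                         annotators=2, decoy_prob=0.2, seed=0)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_phantom_config):
    return generate_phantom(tiny_phantom_config)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_config):
    """Eight 32^3 phantoms with two annotators each."""
    return synthetic_cohort(8, config=tiny_phantom_config, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
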