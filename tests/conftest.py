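import numpy as np
import pytest

from spacecat.synthetic import (SimCountConfig, SimImageConfig,
                                generate_counts,
                                generate_fluorescence_field)


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted-structure dataset: counts, metadata, truth."""
    return generate_counts(SimCountConfig(seed=0))


@pytest.fixture(scope="session")
def default_expr(default_dataset):
    from spacecat.spatial import lognormalize

    counts, meta, truth = default_dataset
    return lognormalize(counts), meta, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Same study conditions but with the border effect switched off."""
    return generate_counts(SimCountConfig(border_effect=0.0, seed=1))


@pytest.fixture(scope="session")
def noiseless_field():
    cfg = SimImageConfig(noise_sd=0.0, uncaging_factor=3.0, seed=2)
    return generate_fluorescence_field(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
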