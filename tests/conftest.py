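import numpy as np
import pytest

from stromascore import ImageSimConfig, simulate_image_pair


@pytest.fixture(scope="session")
def default_pair():
    """One default synthetic slide pair, shared across tests (seed 7)."""
    return simulate_image_pair(ImageSimConfig(seed=7))


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, perfectly aligned pair for exactness checks."""
    from stromascore import AffineTransform2D

    return simulate_image_pair(
        ImageSimConfig(seed=11, noise_sd=0.0, misalignment=AffineTransform2D.identity())
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
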