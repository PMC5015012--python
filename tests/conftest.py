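import numpy as np
import pytest

from mngmm import PhantomSpec, Volume, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, bias-free 96x96 phantom."""
    return simulate(PhantomSpec(shape=(96, 96), seed=3))


@pytest.fixture(scope="session")
def noisy_phantom():
    """5% noise, no bias."""
    return simulate(PhantomSpec(shape=(96, 96), noise_level=5.0, seed=3))


@pytest.fixture(scope="session")
def biased_phantom():
    """3% noise with a strong (80%) bias field."""
    return simulate(
        PhantomSpec(shape=(128, 128), noise_level=3.0, inu_level=80.0, seed=3)
    )


@pytest.fixture()
def tiny_volume(rng):
    """7x7 fully masked random-intensity image with small dynamic range."""
    data = rng.uniform(0.5, 2.5, size=(7, 7))
    return Volume(data, mask=np.ones((7, 7), dtype=bool))


@pytest.fixture()
def three_cluster_values(rng):
    """3000 samples from three well-separated Gaussians (50/120/200, sd 5)."""
    y = np.concatenate(
        [
            rng.normal(50, 5, 1000),
            rng.normal(120, 5, 1000),
            rng.normal(200, 5, 1000),
        ]
    )
    rng.shuffle(y)
    return y
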