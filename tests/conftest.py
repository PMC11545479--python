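import numpy as np
import pytest

from erythrokit import presets
from erythrokit.synthetic import make_surface_texture


@pytest.fixture(scope="session")
def control_texture():
    """One control-preset texture map, shared across metrology tests."""
    return make_surface_texture(presets.TEXTURE_PRESETS["control"], seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def lognormal_sample(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), n))
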