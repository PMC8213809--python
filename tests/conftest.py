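import numpy as np
import pytest

from smlmclassify import LocalizationSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_particle(rng, n=5, dim=2, spread=40.0, sigma_lo=1.0, sigma_hi=4.0,
                    anisotropic=False):
    """Small random localization cloud for oracle tests."""
    coords = rng.uniform(-spread, spread, size=(n, dim))
    sigma = rng.uniform(sigma_lo, sigma_hi, size=n)
    sigma_z = rng.uniform(sigma_lo, 2 * sigma_hi, size=n) \
        if (dim == 3 and anisotropic) else None
    return LocalizationSet(coords, sigma, sigma_z)
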