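"""Shared fixtures: small calibrated phantoms and a fitted parameter field.

The heavy pieces (kinetic calibration, the 64x64 pixel-wise fit) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from iodoperf import default_phantom, fit_field, render_series

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def phantom64():
    """Noise-free reference phantom on a 64x64 grid."""
    return default_phantom(shape=(64, 64), noise_sigma=0.0)


@pytest.fixture(scope="session")
def render64(phantom64):
    return render_series(phantom64)


@pytest.fixture(scope="session")
def fitfield64(render64):
    """Pixel-wise two-step fit of the noise-free 64x64 phantom."""
    return fit_field(render64.series)


@pytest.fixture(scope="session")
def phantom256_noiseless():
    return default_phantom(shape=(256, 256), noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20191105)
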