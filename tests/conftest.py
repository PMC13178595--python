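import numpy as np
import pytest

import fluorocorr as fc


@pytest.fixture(scope="session")
def grid():
    return np.arange(460.0, 661.0, 1.0)


@pytest.fixture(scope="session")
def phantom_library(grid):
    return fc.default_phantom_library(grid)


@pytest.fixture(scope="session")
def liver_library():
    return fc.default_liver_library()


@pytest.fixture(scope="session")
def noiseless_suite():
    """The 7-phantom suite at both excitation tags, noise switched off."""
    return fc.generate_phantom_suite(seed=0, with_noise=False)


@pytest.fixture(scope="session")
def noisy_suite():
    """Default seeded suite: 2% per-repeat noise, 5-repeat averaging."""
    return fc.generate_phantom_suite(seed=0)


def flat_spectrum(grid, value=1.0, kind="raw"):
    return fc.Spectrum(grid, np.full(grid.shape, float(value)), kind)


@pytest.fixture
def small_grid():
    return np.array([500.0, 510.0, 520.0, 530.0])
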