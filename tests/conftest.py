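"""Shared fixtures: default spectrum, bins, desk-scale geometry, phantoms."""

import numpy as np
import pytest

from spcct import config
from spcct.forward import Geometry, simulate_acquisition
from spcct.phantoms import build_tube


@pytest.fixture(scope="session")
def spectrum():
    return config.default_spectrum()


@pytest.fixture(scope="session")
def bins():
    return config.default_bins()


@pytest.fixture(scope="session")
def geometry():
    return config.default_geometry()


@pytest.fixture(scope="session")
def water_disk():
    """Default 12 mm water disk on the 64-voxel grid."""
    return build_tube(0.0, "gold", config.DEFAULT_WATER_DISK_MM, config.DEFAULT_GRID_N)


@pytest.fixture(scope="session")
def acquire(spectrum, bins, geometry):
    """Acquisition helper bound to the default settings."""

    def _acquire(phantom, seed=None, noise=True, flux=config.DEFAULT_FLUX, geo=geometry):
        return simulate_acquisition(
            phantom, spectrum, bins, geo, flux, seed=seed, noise=noise
        )

    return _acquire


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
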