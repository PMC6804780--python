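import numpy as np
import pytest

from ltomo.core import OpticalGrid


@pytest.fixture
def grid2d() -> OpticalGrid:
    """Small 2D (cylinder-geometry) grid: 16 x 1 transverse, 8 slices."""
    return OpticalGrid(nx=16, ny=1, nz=8, dx=0.15, dz=0.15, wavelength=0.6, n0=1.0)


@pytest.fixture
def grid3d() -> OpticalGrid:
    """Small 3D grid in a watery medium."""
    return OpticalGrid(nx=12, ny=10, nz=6, dx=0.15, dz=0.15, wavelength=0.6, n0=1.33)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
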