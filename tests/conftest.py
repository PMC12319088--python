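import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sdism import (
    OpticalConfig,
    bead_phantom,
    estimate_lattice,
    multifocal_sequence,
    register_subimages,
    sample_vda,
    simulate_stack,
)
from sdism.phantoms import Phantom3D

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

VOXEL = (150.0, 65.0, 65.0)
SIZE = 192


@pytest.fixture(scope="session")
def cfg_matched():
    """Matched excitation/emission wavelengths: the idealized symmetric system."""
    return OpticalConfig(wavelength_ex=500.0, wavelength_em=500.0)


@pytest.fixture(scope="session")
def cfg_default():
    return OpticalConfig()


@pytest.fixture(scope="session")
def seq_4_12():
    """The standard 4:12 two-pixel-step scan over a mask covering 192 px."""
    return multifocal_sequence(aperture=4, period=12, step=2, dmd_shape=(248, 248))


@pytest.fixture(scope="session")
def seq_point():
    """Single-pixel apertures: delta-like excitation for matched-PSF studies."""
    return multifocal_sequence(aperture=1, period=12, step=2, dmd_shape=(248, 248))


@pytest.fixture(scope="session")
def uniform_stack(cfg_matched, seq_4_12):
    ph = Phantom3D(values=np.ones((1, SIZE, SIZE)), voxel=VOXEL, kind="uniform")
    return simulate_stack(ph, seq_4_12, cfg_matched, mode="wf", seed=1)


@pytest.fixture(scope="session")
def bead_scene(cfg_matched, seq_point):
    """Sparse sub-resolution beads imaged with delta-like excitation (wf)."""
    ph = bead_phantom(
        (1, SIZE, SIZE),
        voxel=VOXEL,
        n_beads=8,
        bead_diameter=80.0,
        min_separation=2000.0,
        seed=2,
    )
    centers_px = np.array([[c[1], c[2]] for c in ph.meta["centers_nm"]]) / 65.0 - 0.5
    stack = simulate_stack(ph, seq_point, cfg_matched, mode="wf", seed=1)
    return ph, centers_px, stack


@pytest.fixture(scope="session")
def bead_subimages(bead_scene):
    _, centers_px, stack = bead_scene
    lattice = estimate_lattice(stack)
    sset = sample_vda(stack, lattice)
    return centers_px, sset, register_subimages(sset)


def interior_grid_centers(sset, centers_px, margin=7):
    """Scan-grid coordinates of beads whose fit window stays inside the grid."""
    g = sset.to_grid(centers_px)
    h, w = sset.images.shape[2:]
    return [c for c in g if margin < c[0] < h - margin and margin < c[1] < w - margin]
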