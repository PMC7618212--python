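"""Shared fixtures: small seeded synthetic instances."""

import numpy as np
import pytest
from scipy import ndimage

from mcslr.config import ReconConfig, SimulationSpec
from mcslr.sampling import bin_shots, generate_seg_caipi
from mcslr.simulator import make_coil_maps, make_phantom, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smooth_image():
    """Smooth compactly supported complex test image, 64x64."""
    img = np.zeros((64, 64))
    img[20:44, 24:40] = 1.0
    img = ndimage.gaussian_filter(img, 3.0)
    phase = ndimage.gaussian_filter(np.random.default_rng(7).standard_normal((64, 64)), 6.0)
    return (img * np.exp(1j * phase)).astype(np.complex128)


@pytest.fixture(scope="session")
def phantom96():
    return make_phantom((96, 96), seed=5)


@pytest.fixture(scope="session")
def scheme_small():
    """32x32 grid, R=2x2, 8 shots, 2 groups, 2-shot subdivisions."""
    return bin_shots(
        generate_seg_caipi((32, 32), (2, 2), 8, n_interleaves=2), 2, 2
    )


@pytest.fixture(scope="session")
def sens_small():
    return make_coil_maps((32, 32), 4, seed=3)


@pytest.fixture(scope="session")
def sim_small():
    """Motion-free, noise-free 64x64 simulated instance (fast)."""
    spec = SimulationSpec(
        image_shape=(64, 64), n_coils=4, n_shots=8, n_groups=2,
        shots_per_subdivision=4, n_volumes=1, rot_range_deg=0.0,
        trans_range_mm=0.0, snr_db=None, phase_amplitude_rad=1.0, seed=11,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def fast_config():
    return ReconConfig(
        admm_iters=2, cg_iters=8, outer_iters_max=5, mcsense_iters_max=4
    )
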