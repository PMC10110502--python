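import numpy as np
import pytest

from pgcprot import synthetic as sy


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def disk_mask():
    """Solid disk radius 20 centered at (32, 32) in a 64x64 frame."""
    yy, xx = np.mgrid[0:64, 0:64]
    return np.hypot(yy - 32, xx - 32) <= 20


@pytest.fixture
def random_blob(rng):
    """A filled random blob: union of a few disks, single component."""

    def make(seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        yy, xx = np.mgrid[0:48, 0:48]
        mask = np.zeros((48, 48), dtype=bool)
        cy, cx = 24.0, 24.0
        for _ in range(4):
            rad = r.uniform(4, 10)
            mask |= np.hypot(yy - cy, xx - cx) <= rad
            cy += r.uniform(-5, 5)
            cx += r.uniform(-5, 5)
        return mask

    return make


@pytest.fixture
def quiet_cell_scene():
    """Noise-free, bleb-free, stationary single-cell movie."""
    params = sy.CellMovieParams(n_frames=2, noise_sd=0.0, bleb_rate_per_min=0.0)
    return sy.generate_cell_movie(params, seed=11)
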