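
import numpy as np
import pytest

import hdrneedle as hn


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom (64x64x16 @ 0.8/0.8/5.0 mm, 4 needles)."""
    return hn.make_phantom(hn.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast phantom for I/O and pipeline plumbing tests."""
    cfg = hn.PhantomConfig(grid_shape=(32, 32, 8), n_needles=3,
                           min_separation_mm=2.0, seed=3)
    return hn.make_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def straight_tube_mask(shape=(16, 16, 8), spacing=(1.0, 1.0, 1.0),
                       center=(8, 8), radius_vox=1.6, z_slices=None):
    """Rasterize a vertical tube; shared helper for digitization tests."""
    data = np.zeros(shape, dtype=np.uint8)
    xs, ys = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    sel = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius_vox ** 2
    ks = range(shape[2]) if z_slices is None else z_slices
    for k in ks:
        data[:, :, k][sel] = 1
    return hn.Volume(data, spacing)
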