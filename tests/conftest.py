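import numpy as np
import pytest
from hypothesis import settings

import murineseg as ms

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_mouse():
    """One noiseless phantom mouse with its region parts, shared read-only."""
    spec = ms.PhantomSpec(noise_sd_hu=0.0)
    vol, mask, parts = ms.generate_mouse(spec, seed=0, parts=True)
    return spec, vol, mask, parts


@pytest.fixture(scope="session")
def noisy_mouse():
    spec = ms.PhantomSpec()  # default 20 HU noise
    vol, mask = ms.generate_mouse(spec, seed=0)
    return spec, vol, mask


def random_blob_mask(rng, shape=(10, 10, 10), n_seeds=3, spacing=(0.35, 0.35, 0.35)):
    """Small random mask: union of a few random boxes/balls, possibly empty-ish."""
    grid = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = rng.integers(0, shape[0], 3)
        r = rng.integers(1, 4)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        grid |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r * r
    if not grid.any():
        grid[tuple(rng.integers(0, shape[0], 3))] = True
    return ms.Mask(grid.astype(np.uint8), spacing, (0.0, 0.0, 0.0))
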