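import numpy as np
import pytest

from adctexture import QuantizedVOI, VOIMask


def make_voi(levels: np.ndarray, n_bins: int | None = None, mask: np.ndarray | None = None):
    """Wrap an integer level grid (0 = outside) into a QuantizedVOI."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = levels > 0
    m = VOIMask(data=mask)
    if n_bins is None:
        n_bins = int(levels.max())
    return QuantizedVOI(levels=levels, n_bins=n_bins, mask=m)


@pytest.fixture
def random_voi_factory():
    """Random small VOIs with a given gray-level count and random mask."""

    def factory(rng: np.random.Generator, shape=(5, 5, 4), n_levels=4, p_mask=0.8):
        mask = rng.random(shape) < p_mask
        if not mask.any():
            mask.flat[0] = True
        levels = np.zeros(shape, dtype=np.int32)
        levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
        return make_voi(levels, n_bins=n_levels, mask=mask)

    return factory
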