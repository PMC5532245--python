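import numpy as np
import pytest

from soilcap import LandCoverGrid, SoilSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_seea_pair(rng, max_side=50, nodata_frac=0.1):
    """A random co-registered SEEA grid pair with a shared nodata mask."""
    shape = (int(rng.integers(1, max_side + 1)), int(rng.integers(1, max_side + 1)))
    c0 = rng.integers(1, 15, size=shape)
    c1 = np.where(rng.random(shape) < 0.3, rng.integers(1, 15, size=shape), c0)
    nodata = rng.random(shape) < nodata_frac
    c0[nodata] = 0
    c1[nodata] = 0
    area = float(rng.choice([0.01, 0.25, 1.0]))
    return (
        LandCoverGrid(c0, area, epoch="t0"),
        LandCoverGrid(c1, area, epoch="t1"),
    )


@pytest.fixture
def grid_pair(rng):
    return random_seea_pair(rng)


@pytest.fixture
def toy_samples():
    mk = lambda i, r, c, cov, soc, ph, peat=False: SoilSample(f"s{i:03d}", r, c, cov, soc, ph, peat)
    return [
        mk(0, 0, 0, 2, 15.0, 6.8),
        mk(1, 0, 3, 2, 25.0, 7.1),
        mk(2, 2, 1, 2, 45.0, 6.2),
        mk(3, 4, 4, 6, 150.0, 4.6),
        mk(4, 3, 0, 6, 80.0, 4.9, peat=True),
        mk(5, 1, 2, 6, 35.0, 5.4),
    ]
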