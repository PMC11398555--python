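import numpy as np
import pytest

from myodti import PackingParams, FiberLabelMap, PGSEProtocol, generate_fiber_packing
from myodti.morphometry import fiber_stats


@pytest.fixture(scope="session")
def packing_600um():
    """A 600x600 um packing at 1 um/px: ~400 fibers, mean 30 um, CV 0.3."""
    params = PackingParams(
        region_width_um=600, region_height_um=600, mean_diameter_um=30,
        diameter_cv=0.3, gap_width_um=3.0, pixel_size_um=1.0, seed=1,
    )
    return generate_fiber_packing(params)


@pytest.fixture(scope="session")
def packing_600um_stats(packing_600um):
    return fiber_stats(packing_600um)


def make_disc_map(diameter_um=40.0, pixel_size_um=0.22, margin_um=5.0):
    r = diameter_um / 2.0
    n = int(round((diameter_um + 2 * margin_um) / pixel_size_um))
    c = n * pixel_size_um / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    d = np.hypot((xx + 0.5) * pixel_size_um - c, (yy + 0.5) * pixel_size_um - c)
    return FiberLabelMap(labels=(d < r).astype(np.int32), pixel_size_um=pixel_size_um)


@pytest.fixture(scope="session")
def disc_map_40um():
    """Rasterized 40 um disc at the slide-scanner resolution (0.22 um/px)."""
    return make_disc_map()


@pytest.fixture(scope="session")
def protocol():
    """The emulated PGSE protocol: b=500, delta/Delta=3.1/15, 30 dirs, 5 b0."""
    return PGSEProtocol()
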