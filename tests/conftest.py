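import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from cardiomorph.morphometry import RegionRecord, extract_regions


def ellipse_mask(a: float, b: float, rotation: float = 0.0, pad: int = 6) -> np.ndarray:
    """Boolean mask of a rasterised ellipse with semi-axes (a, b) in px."""
    n = int(2 * max(a, b) + 2 * pad)
    rr, cc = draw_ellipse(n / 2, n / 2, a, b, shape=(n, n), rotation=rotation)
    m = np.zeros((n, n), bool)
    m[rr, cc] = True
    return m


def single_region(mask: np.ndarray) -> RegionRecord:
    regions = extract_regions(mask.astype(np.int32))
    assert len(regions) == 1
    return regions[0]


@pytest.fixture
def circle_region():
    def _make(radius: float) -> RegionRecord:
        return single_region(ellipse_mask(radius, radius))

    return _make
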