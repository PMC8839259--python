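import numpy as np
import pytest

from bandstraight.lane import LaneImage
from bandstraight.synthesize import FWHM_TO_SIGMA


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_band_lane(
    height=120,
    width=40,
    positions=(30, 60, 90),
    amplitude=50.0,
    fwhm=10.0,
    base=5.0,
    tilt=0.0,
):
    """Signal-polarity lane with horizontal Gaussian bands.

    ``tilt`` shears every band midline by tilt*(x - (width-1)/2) pixels.
    """
    ys = np.arange(height, dtype=float)[:, None]
    xs = np.arange(width, dtype=float)[None, :]
    sigma = fwhm * FWHM_TO_SIGMA
    img = np.full((height, width), base)
    for p in np.atleast_1d(positions):
        centre = p + tilt * (xs - (width - 1) / 2.0)
        img = img + amplitude * np.exp(-((ys - centre) ** 2) / (2 * sigma**2))
    return LaneImage(img)
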