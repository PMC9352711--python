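import numpy as np
import pytest

from tlcquant import synthetic, validation
from tlcquant.imaging import LINEAR, RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def gradient_image(rng):
    """A smooth linear-intensity grayscale image."""
    yy, xx = np.mgrid[0:120, 0:160]
    pix = 0.3 + 0.3 * xx / 159 + 0.2 * yy / 119
    return RasterImage(pix, LINEAR)


@pytest.fixture
def standard_scene():
    """One rendered noiseless repeatability plate plus its annotations."""
    spec = synthetic.standard_scenarios()["repeatability_85"]
    photo, truth = synthetic.render_plate(spec, seed=11)
    ann = validation.annotations_from_truth(truth, photo.width, photo.height)
    return spec, photo, truth, ann
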