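import numpy as np
import pytest

from pidquant import FieldImage, LabelMask
from pidquant.spot_detection import SpotSet


def plant_gaussians(shape, positions, amplitude, sigma_px, background=10.0):
    """Render Gaussian puncta at (y, x) subpixel positions over a flat background."""
    img = np.full(shape, float(background))
    half = int(np.ceil(4 * sigma_px))
    for y, x in positions:
        y0, y1 = max(0, int(round(y)) - half), min(shape[0], int(round(y)) + half + 1)
        x0, x1 = max(0, int(round(x)) - half), min(shape[1], int(round(x)) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2)
        )
    return img


def square_mask(shape, squares, pixel_size_um=0.5, kind="nucleus"):
    """Label mask from a list of (label, y0, y1, x0, x1) squares."""
    labels = np.zeros(shape, dtype=np.int64)
    for lab, y0, y1, x0, x1 in squares:
        labels[y0:y1, x0:x1] = lab
    return LabelMask(labels, pixel_size_um=pixel_size_um, kind=kind)


def spotset(xy, field_id="field0"):
    """SpotSet from a list of (x, y) pairs with unit intensities."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return SpotSet(xy[:, 0], xy[:, 1], np.ones(len(xy)), field_id=field_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
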