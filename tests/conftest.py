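import math

import numpy as np
import pytest

from stromakit.qpi import PhaseFrame, SegmentationParams


def render_ellipse(
    shape=(128, 128),
    center=None,
    a=30.0,
    b=10.0,
    theta=0.0,
    peak=1.0,
    power=4,
    pixel_size=1.0,
):
    """Super-Gaussian elliptical blob whose half-max contour is the nominal
    ellipse with semi-axes (a, b) in physical units."""
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) * pixel_size / a
    v = (-dx * st + dy * ct) * pixel_size / b
    rho2 = u * u + v * v
    return peak * np.exp(-math.log(2.0) * rho2**power)


@pytest.fixture
def ellipse_frame():
    """Isolated 30 x 10 um ellipse at 1 um/px on a clean background."""
    px = render_ellipse(shape=(128, 128), a=30, b=10, peak=1.0)
    return PhaseFrame(pixels=px, pixel_size=1.0, wavelength=0.6)


@pytest.fixture
def small_params():
    """Segmentation parameters scaled to the small unit-test fixtures."""
    return SegmentationParams(
        rolling_ball_radius=40.0, smooth_sigma=1.0, min_seed_distance=10,
        threshold=0.5,
    )
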