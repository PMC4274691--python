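import numpy as np
import pytest

from muscleseg import SyntheticSpec, generate_muscle_image


@pytest.fixture(scope="session")
def synthetic_low():
    """One seeded low-noise synthetic section with its ground truth."""
    spec = SyntheticSpec(rng_seed=7, noise_level="low")
    return generate_muscle_image(spec)


@pytest.fixture(scope="session")
def small_synthetic():
    """A smaller, faster synthetic section (256x256, 9 fibres)."""
    spec = SyntheticSpec(height=256, width=256, n_seeds=9, rng_seed=3)
    return generate_muscle_image(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rasterize_ellipse(shape, center, semi_axes, theta=0.0):
    """Boolean raster of an ellipse; the analytic fixture for morphometry."""
    h, w = shape
    cy, cx = center
    ry, rx = semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    c, s = np.cos(theta), np.sin(theta)
    u = c * (xx - cx) + s * (yy - cy)
    v = -s * (xx - cx) + c * (yy - cy)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
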