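import numpy as np
import pytest

from lungnlb import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_phantom():
    return synthetic.make_phantom(synthetic.draw_spec("benign", seed=11))


@pytest.fixture(scope="session")
def malignant_phantom():
    return synthetic.make_phantom(synthetic.draw_spec("malignant", seed=11))


def disk_mask(size: int, radius: float, center=None) -> np.ndarray:
    """Discretized disk: pixels within `radius` of the center."""
    cy, cx = center if center is not None else (size / 2, size / 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - cy, xx - cx) <= radius


def star_mask(size: int, radius: float, spikes: int, amplitude: float) -> np.ndarray:
    """Star-shaped region with cosine-modulated boundary radius."""
    cy = cx = size / 2
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    return np.hypot(dy, dx) <= radius * (1 + amplitude * np.cos(spikes * theta))
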