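import numpy as np
import pytest

from vesselrad import PhantomSpec, generate_phantom


def make_tube_image(size=128, radius=2.0, orientation="h", value=1.0, profile="uniform"):
    """A single straight tube through the image center, rendered cleanly."""
    img = np.zeros((size, size))
    c = size // 2
    rows, cols = np.mgrid[0:size, 0:size]
    d = np.abs(rows - c) if orientation == "h" else np.abs(cols - c)
    inside = d <= radius
    if profile == "uniform":
        img[inside] = value
    else:
        img = np.where(inside, value * np.exp(-(d**2) / (2 * (radius / 2.0) ** 2)), 0.0)
    return img


@pytest.fixture(scope="session")
def small_phantom():
    """A quick, clean phantom (no degradation) with exact rasterized truth."""
    spec = PhantomSpec(image_size=192, n_branch_target=12, root_radius=4.0,
                       min_radius=1.5, seed=7)
    return generate_phantom(spec, resize_erode_factor=1, erode=False)


@pytest.fixture(scope="session")
def degraded_phantom():
    """A phantom under the standard resize-erode degradation."""
    spec = PhantomSpec(image_size=256, n_branch_target=20, root_radius=5.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
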