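import numpy as np
import pytest

from casct.geometry import Image, make_fan_geometry, pixel_centers


@pytest.fixture(scope="session")
def tiny_geometry():
    """8x8 grid, 16 views, 21 bins — small enough for dense-matrix oracles."""
    return make_fan_geometry(8, 16, 21, 10.0, 3.0)


@pytest.fixture(scope="session")
def small_geometry():
    """64x64 grid at the full 360-view protocol, scaled-down detector."""
    return make_fan_geometry(64, 360, 111, 39.7, 12.7)


@pytest.fixture(scope="session")
def full_geometry():
    """The full-scale acquisition geometry."""
    return make_fan_geometry(256, 360, 439, 39.7, 12.7)


def analytic_disk(geometry, radius, mu, supersample=4):
    """Anti-aliased rasterization of a centered disk of attenuation mu."""
    n = geometry.image_side
    s = supersample
    px = geometry.pixel_size / s
    half = (n * s - 1) / 2.0
    c = (np.arange(n * s) - half) * px
    X, Y = np.meshgrid(c, -c)
    fine = (X**2 + Y**2 <= radius**2).astype(float)
    return Image(mu * fine.reshape(n, s, n, s).mean(axis=(1, 3)))


@pytest.fixture(scope="session")
def disk_image_small(small_geometry):
    return analytic_disk(small_geometry, 8.0, 0.2)
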