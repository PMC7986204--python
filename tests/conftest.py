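import numpy as np
import pytest

from gtvgen.imaging_io import BinaryMask, GridGeometry
from gtvgen.phantom import PhantomConfig, render_phase_series


@pytest.fixture(scope="session")
def quiet_config():
    """Default-geometry phantom with noise, blur and chest wall disabled."""
    return PhantomConfig(noise_sd_hu=0.0, blur_sigma_mm=0.0, chest_wall=False)


@pytest.fixture(scope="session")
def noisy_phantom():
    """One rendered phantom at the default study conditions (noise SD 20 HU)."""
    cfg = PhantomConfig(seed=11)
    return cfg, *render_phase_series(cfg)


@pytest.fixture
def unit_grid():
    """A small isotropic 1 mm grid centred on the origin."""
    shape = (48, 48, 48)
    origin = tuple(-(n - 1) / 2.0 for n in shape)
    return GridGeometry(shape, (1.0, 1.0, 1.0), origin)


def sphere_mask(geometry: GridGeometry, center_mm, radius_mm) -> BinaryMask:
    x = geometry.axis_coords(0)[:, None, None]
    y = geometry.axis_coords(1)[None, :, None]
    z = geometry.axis_coords(2)[None, None, :]
    c = np.asarray(center_mm, float)
    return BinaryMask(
        geometry,
        (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius_mm**2,
    )
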