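import dataclasses

import numpy as np
import pytest

from focigap import SceneConfig
from focigap.core import FieldImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_config():
    """A fast 256x256 cell scene used by several end-to-end tests."""
    return dataclasses.replace(
        SceneConfig(), fov_px=(256, 256), n_cells=20, coloc_fraction=0.0, seed=11
    )


def gaussian_spot_image(
    shape=(64, 64),
    centers=((32.0, 32.0),),
    amplitude=300.0,
    sigma=1.2,
    background=0.0,
    pixel_size_nm=109.0,
):
    """Noise-free sum of Gaussians sampled at pixel centers (test helper)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for x0, y0 in centers:
        img += amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)
        )
    return FieldImage(img, pixel_size_nm)
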