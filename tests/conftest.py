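import numpy as np
import pytest

from capquant.geometry import ClassLabel, ImageMeta, InstanceMask
from capquant.synth import easy_scene_spec, generate_scene


@pytest.fixture
def meta512() -> ImageMeta:
    return ImageMeta()


@pytest.fixture
def meta32() -> ImageMeta:
    return ImageMeta(width_px=32, height_px=32, fov_um=(42.5 / 16, 42.5 / 16))


def make_mask(shape, coords, label=ClassLabel.CM, score=None) -> InstanceMask:
    raster = np.zeros(shape, dtype=bool)
    for r, c in coords:
        raster[r, c] = True
    return InstanceMask(raster, label, score)


def block_mask(shape, r0, r1, c0, c1, label=ClassLabel.CM, score=None) -> InstanceMask:
    raster = np.zeros(shape, dtype=bool)
    raster[r0:r1, c0:c1] = True
    return InstanceMask(raster, label, score)


@pytest.fixture(scope="session")
def easy_scene():
    """One noise-free low-irregularity 256 px scene, shared across tests."""
    spec = easy_scene_spec(seed=11)
    image, masks = generate_scene(spec)
    return spec, image, masks
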