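import numpy as np
import pytest

from wltb.phantom import PhantomConfig
from wltb.volumes import ImageVolume, SegmentationSet


def sphere_mask(shape, center_mm, radius_mm, spacing):
    """Digital sphere: voxels whose centers lie within radius of center."""
    spacing = np.asarray(spacing, float)
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return d2 <= radius_mm**2


def make_seg(lesion_mask, spacing=(1.0, 1.0, 1.0), liver_mask=None, lobe_split_x=None):
    """SegmentationSet around a given lesion mask; liver defaults to the full grid."""
    from scipy import ndimage

    lesion_mask = np.asarray(lesion_mask, bool)
    if liver_mask is None:
        liver_mask = np.ones_like(lesion_mask)
    lobes = np.zeros(lesion_mask.shape, dtype=np.int16)
    split = lesion_mask.shape[0] // 2 if lobe_split_x is None else lobe_split_x
    lobes[:split][liver_mask[:split]] = 1
    lobes[split:][liver_mask[split:]] = 2
    labels, _ = ndimage.label(lesion_mask, structure=np.ones((3, 3, 3)))
    return SegmentationSet(liver_mask, lobes, labels, spacing)


@pytest.fixture(scope="session")
def small_config():
    """Coarse, quick phantom configuration used across tests."""
    return PhantomConfig(
        subjects=8,
        seed=11,
        grid_shape=(48, 48, 36),
        voxel_spacing=(3.0, 3.0, 3.0),
        liver_semi_axes=(55.0, 45.0, 38.0),
    )


@pytest.fixture
def constant_image():
    def _make(shape, value, spacing=(1.0, 1.0, 1.0)):
        return ImageVolume(np.full(shape, float(value)), spacing)

    return _make
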