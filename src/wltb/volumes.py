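"""In-memory containers for CT volumes and their segmentations.

The package works on co-registered grids: a scalar attenuation volume in
Hounsfield units (HU) and a set of label volumes (liver mask, functional lobe
labels, per-lesion labels) sharing the same shape and voxel spacing.

Axis convention: array axis 0 = x (left-right), axis 1 = y
(anterior-posterior), axis 2 = z (cranio-caudal).  Voxel centers sit at
``index * spacing`` millimetres; the NIfTI affine written by :func:`save_nifti`
carries the spacing on its diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "SegmentationSet",
    "LOBE_LEFT",
    "LOBE_RIGHT",
    "save_nifti",
    "load_nifti",
]

#: integer codes used in ``SegmentationSet.lobe_labels``
LOBE_LEFT = 1
LOBE_RIGHT = 2


@dataclass
class ImageVolume:
    """3D attenuation grid (HU) with anisotropic voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SegmentationSet:
    """Liver mask, lobe labels and lesion label map on a shared grid.

    ``lesion_labels`` assigns one positive integer per 26-connected lesion
    (0 = background).  ``lobe_labels`` uses :data:`LOBE_LEFT` /
    :data:`LOBE_RIGHT` and partitions the liver mask.
    """

    liver_mask: np.ndarray
    lobe_labels: np.ndarray
    lesion_labels: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.liver_mask = np.asarray(self.liver_mask).astype(bool)
        self.lobe_labels = np.asarray(self.lobe_labels).astype(np.int16)
        self.lesion_labels = np.asarray(self.lesion_labels).astype(np.int32)
        shapes = {self.liver_mask.shape, self.lobe_labels.shape, self.lesion_labels.shape}
        if len(shapes) != 1:
            raise ValueError(f"segmentation grids disagree in shape: {shapes}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.liver_mask.shape

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.lesion_labels > 0

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_labels.max())

    def validate(self) -> list[str]:
        """Return a list of consistency problems (empty when clean)."""
        problems: list[str] = []
        outside = int(np.count_nonzero(self.lesion_mask & ~self.liver_mask))
        if outside:
            problems.append(f"{outside} lesion voxel(s) outside the liver mask")
        if np.any((self.lobe_labels > 0) != self.liver_mask):
            problems.append("lobe labels do not partition the liver mask")
        labels = np.unique(self.lesion_labels)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            problems.append("lesion labels are not consecutive 1..N")
        return problems


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(path, array: np.ndarray, spacing: tuple[float, float, float]) -> None:
    """Write a 3D (or 4D) array as NIfTI with spacing on the affine diagonal."""
    img = nib.Nifti1Image(np.asarray(array), _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI file, returning (array, spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing
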