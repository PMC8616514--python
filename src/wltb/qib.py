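"""Geometric and first-order whole-liver tumor burden (WLTB) biomarkers.

Per subject these operations reduce the union of segmented liver metastases
to scalar imaging biomarkers: mean attenuation, absolute and relative tumor
volume, the tumor burden score TBS = sqrt(N^2 + D^2) (N lesions, largest
diameter D in cm), bilobar disease, the geometric metastatic spread MSx/MSy/
MSz (per-axis extent of the lesion union, cm) and the surface-area-to-volume
ratio of the lesion union (1/cm).

Subjects without any lesion are expected to be excluded upstream; operations
that are undefined on an empty tumor burden return NaN with a warning rather
than fabricating zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .volumes import LOBE_LEFT, LOBE_RIGHT, ImageVolume, SegmentationSet

__all__ = [
    "LesionRecord",
    "lesion_inventory",
    "tumor_burden_score",
    "bilobar_disease",
    "volume_features",
    "mean_attenuation",
    "geometric_metastatic_spread",
    "surface_area_to_volume",
    "lesion_surface_area_mm2",
    "max_pairwise_distance",
]

_LOBE_NAMES = {LOBE_LEFT: "left", LOBE_RIGHT: "right"}


@dataclass
class LesionRecord:
    """Per-lesion bookkeeping behind the geometric biomarkers."""

    id: int
    voxel_count: int
    volume_cm3: float
    centroid_mm: tuple[float, float, float]
    max_diameter_cm: float
    lobe_membership: tuple[str, ...]


def max_pairwise_distance(points: np.ndarray) -> float:
    """Largest Euclidean distance between any two points (mm in, mm out).

    Uses the convex hull first (the diameter of a finite point set is attained
    on its hull) and falls back to exhaustive pairwise distances for tiny or
    degenerate (flat) clouds where qhull fails.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    if len(pts) < 2:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # coplanar/collinear clouds: brute force below
    return float(pdist(pts).max())


def lesion_inventory(seg: SegmentationSet, spacing=None) -> list[LesionRecord]:
    """Enumerate lesions with volume, centroid, diameter and lobe membership.

    The maximum diameter is the largest distance between voxel centers of the
    lesion, measured in physical mm (exact for convex voxel clouds via the
    convex hull), reported in cm.  ``lobe_membership`` lists every lobe the
    lesion intersects, so a single lesion straddling the lobe plane belongs
    to both.
    """
    spacing = np.asarray(seg.spacing if spacing is None else spacing, dtype=float)
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    records: list[LesionRecord] = []
    for lesion_id in range(1, seg.n_lesions + 1):
        idx = np.argwhere(seg.lesion_labels == lesion_id)
        if idx.size == 0:
            continue
        pts_mm = idx * spacing
        lobes = np.unique(seg.lobe_labels[tuple(idx.T)])
        membership = tuple(_LOBE_NAMES[l] for l in lobes if l in _LOBE_NAMES)
        records.append(
            LesionRecord(
                id=lesion_id,
                voxel_count=len(idx),
                volume_cm3=len(idx) * voxel_cm3,
                centroid_mm=tuple(pts_mm.mean(axis=0)),
                max_diameter_cm=max_pairwise_distance(pts_mm) / 10.0,
                lobe_membership=membership,
            )
        )
    return records


def tumor_burden_score(inventory: list[LesionRecord]) -> float:
    """TBS = sqrt(N^2 + D^2): lesion count and largest lesion diameter (cm)."""
    if not inventory:
        warnings.warn("tumor burden score undefined for an empty lesion inventory")
        return float("nan")
    n = len(inventory)
    d = max(rec.max_diameter_cm for rec in inventory)
    return float(np.hypot(n, d))


def bilobar_disease(inventory: list[LesionRecord]) -> bool:
    """True iff lesion voxels occupy both the left and the right lobe.

    Decided at voxel level: one lesion crossing the lobe plane is bilobar.
    """
    seen: set[str] = set()
    for rec in inventory:
        seen.update(rec.lobe_membership)
    return "left" in seen and "right" in seen


def volume_features(seg: SegmentationSet, spacing=None) -> dict[str, float]:
    """Absolute lesion volume (cm^3) and volume relative to the liver (%).

    The liver volume includes lesion voxels, so the relative volume reaches
    100% when lesions fill the entire liver.
    """
    spacing = np.asarray(seg.spacing if spacing is None else spacing, dtype=float)
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    liver_vox = int(np.count_nonzero(seg.liver_mask))
    if liver_vox == 0:
        raise ValueError("empty liver mask: liver volume must be positive")
    lesion_vox = int(np.count_nonzero(seg.lesion_mask))
    return {
        "volume_cm3": lesion_vox * voxel_cm3,
        "relative_volume_pct": 100.0 * lesion_vox / liver_vox,
    }


def mean_attenuation(image: ImageVolume, seg: SegmentationSet) -> float:
    """Arithmetic mean HU over the union of lesion voxels."""
    mask = seg.lesion_mask
    if not mask.any():
        warnings.warn("mean attenuation undefined: no lesion voxels")
        return float("nan")
    return float(image.values[mask].mean())


def geometric_metastatic_spread(
    seg: SegmentationSet,
    spacing=None,
    mode: str = "voxels",
    inventory: list[LesionRecord] | None = None,
) -> dict[str, float]:
    """Per-axis extent of the metastases (MSx, MSy, MSz) in cm.

    ``mode='voxels'`` (default) measures max minus min physical coordinate of
    all lesion voxel centers per scanner axis; ``mode='centroids'`` uses the
    lesion centroids instead (requires ``inventory``).
    """
    spacing = np.asarray(seg.spacing if spacing is None else spacing, dtype=float)
    if mode == "voxels":
        idx = np.argwhere(seg.lesion_mask)
        if idx.size == 0:
            warnings.warn("geometric metastatic spread undefined: no lesions; returning zeros")
            return {"msx_cm": 0.0, "msy_cm": 0.0, "msz_cm": 0.0}
        pts = idx * spacing
    elif mode == "centroids":
        if inventory is None:
            inventory = lesion_inventory(seg, spacing)
        if not inventory:
            warnings.warn("geometric metastatic spread undefined: no lesions; returning zeros")
            return {"msx_cm": 0.0, "msy_cm": 0.0, "msz_cm": 0.0}
        pts = np.asarray([rec.centroid_mm for rec in inventory])
    else:
        raise ValueError(f"unknown spread mode {mode!r}")
    extent_cm = (pts.max(axis=0) - pts.min(axis=0)) / 10.0
    return {"msx_cm": float(extent_cm[0]), "msy_cm": float(extent_cm[1]), "msz_cm": float(extent_cm[2])}


def lesion_surface_area_mm2(mask: np.ndarray, spacing, method: str = "mesh") -> float:
    """Surface area of a binary lesion-union mask, in mm^2.

    ``method='mesh'`` (default) triangulates the 0.5 iso-surface with
    marching cubes in physical units.  The binary mask is lightly
    anti-aliased first (Gaussian, 0.6 voxel): marching cubes on a raw binary
    volume inherits the voxel staircase and overestimates smooth surfaces by
    ~8-9%, while the anti-aliased iso-surface is within a few percent of the
    analytic area for digital spheres from 3 voxels radius up.
    ``method='voxel'`` counts exposed voxel faces, which overestimates smooth
    surfaces by up to ~50% and is provided for comparison only.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return 0.0
    spacing = tuple(float(s) for s in spacing)
    if method == "mesh":
        from scipy import ndimage

        padded = ndimage.gaussian_filter(np.pad(mask, 2).astype(np.float32), sigma=0.6)
        if padded.max() < 0.5:
            # a near-single-voxel mask smooths below the iso-level; mesh the
            # raw binary mask instead (anti-aliasing is moot at that size)
            padded = np.pad(mask, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        return float(measure.mesh_surface_area(verts, faces))
    if method == "voxel":
        area = 0.0
        face_areas = (
            spacing[1] * spacing[2],
            spacing[0] * spacing[2],
            spacing[0] * spacing[1],
        )
        padded = np.pad(mask, 1)
        for axis, fa in enumerate(face_areas):
            diff = np.diff(padded.astype(np.int8), axis=axis)
            area += float(np.count_nonzero(diff)) * fa
        return area
    raise ValueError(f"unknown surface method {method!r}")


def surface_area_to_volume(seg: SegmentationSet, spacing=None, method: str = "mesh") -> float:
    """SA/V of the lesion union in 1/cm; quantifies dispersion of metastases.

    For a single sphere of radius r this is 3/r; splitting the same volume
    into many small lesions increases it.
    """
    spacing = np.asarray(seg.spacing if spacing is None else spacing, dtype=float)
    mask = seg.lesion_mask
    volume_mm3 = float(np.count_nonzero(mask)) * float(np.prod(spacing))
    if volume_mm3 == 0:
        warnings.warn("SA/V undefined: lesion volume is zero")
        return float("nan")
    area_mm2 = lesion_surface_area_mm2(mask, spacing, method=method)
    return float(area_mm2 / volume_mm3) * 10.0  # 1/mm -> 1/cm
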