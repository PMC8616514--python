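"""Assembly of the full 13-biomarker feature vector per subject."""

from __future__ import annotations

import numpy as np

from . import qib, radiomics
from .volumes import ImageVolume, SegmentationSet

#: canonical column order of the per-subject feature row
FEATURE_COLUMNS = [
    "attenuation_hu",
    "volume_cm3",
    "relative_volume_pct",
    "tbs",
    "bilobar",
    "energy",
    "compactness",
    "glrlm_nonuniformity",
    "wavelet_nonuniformity",
    "msx_cm",
    "msy_cm",
    "msz_cm",
    "sa_v_per_cm",
]


def axial_max_diameter_cm(seg: SegmentationSet) -> float:
    """Largest in-plane (x-y) lesion diameter over all axial slices, in cm."""
    spacing = np.asarray(seg.spacing)
    best = 0.0
    for lesion_id in range(1, seg.n_lesions + 1):
        idx = np.argwhere(seg.lesion_labels == lesion_id)
        if idx.size == 0:
            continue
        for z in np.unique(idx[:, 2]):
            pts = idx[idx[:, 2] == z][:, :2] * spacing[:2]
            best = max(best, qib.max_pairwise_distance(pts))
    return best / 10.0


def extract_features(
    image: ImageVolume,
    seg: SegmentationSet,
    disc: radiomics.DiscretizationConfig | None = None,
    wcfg: radiomics.WaveletConfig | None = None,
    diameter_mode: str = "3d",
    spread_mode: str = "voxels",
    surface_method: str = "mesh",
) -> dict[str, float]:
    """Compute the 13 whole-liver tumor burden biomarkers for one subject.

    ``diameter_mode`` selects the lesion diameter feeding the tumor burden
    score: "3d" (maximum pairwise distance, default) or "axial" (largest
    in-plane diameter, RECIST-style).
    """
    if image.shape != seg.shape:
        raise ValueError(f"image {image.shape} and segmentation {seg.shape} grids differ")
    disc = disc or radiomics.DiscretizationConfig()
    wcfg = wcfg or radiomics.WaveletConfig()
    inventory = qib.lesion_inventory(seg)
    mask = seg.lesion_mask

    if diameter_mode == "3d":
        tbs = qib.tumor_burden_score(inventory)
    elif diameter_mode == "axial":
        n = len(inventory)
        tbs = float(np.hypot(n, axial_max_diameter_cm(seg))) if n else float("nan")
    else:
        raise ValueError(f"unknown diameter mode {diameter_mode!r}")

    vol = qib.volume_features(seg)
    spread = qib.geometric_metastatic_spread(seg, mode=spread_mode, inventory=inventory)
    surface_mm2 = qib.lesion_surface_area_mm2(mask, seg.spacing, method="mesh")
    row = {
        "attenuation_hu": qib.mean_attenuation(image, seg),
        "volume_cm3": vol["volume_cm3"],
        "relative_volume_pct": vol["relative_volume_pct"],
        "tbs": tbs,
        "bilobar": float(qib.bilobar_disease(inventory)),
        "energy": radiomics.first_order_energy(image.values, mask),
        "compactness": radiomics.shape_compactness(mask, seg.spacing, surface_area_mm2=surface_mm2),
        "glrlm_nonuniformity": radiomics.glrlm_gray_level_nonuniformity(image.values, mask, disc),
        "wavelet_nonuniformity": radiomics.wavelet_gln(image.values, mask, wcfg, disc),
        **spread,
        "sa_v_per_cm": (
            surface_mm2 / (vol["volume_cm3"] * 1000.0) * 10.0
            if surface_method == "mesh" and vol["volume_cm3"] > 0
            else qib.surface_area_to_volume(seg, method=surface_method)
        ),
    }
    return {k: row[k] for k in FEATURE_COLUMNS}
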