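"""Four-feature CT radiomics signature on the whole-liver tumor burden.

The signature comprises first-order energy, shape compactness, gray-level
run-length matrix (GLRLM) gray-level nonuniformity (GLN), and the same GLN
on a wavelet high-pass sub-band.  Definitions follow the Image Biomarker
Standardisation Initiative conventions:

* energy = sum of squared raw HU over the region (no intensity shift);
* compactness (variant 1) = V / (sqrt(pi) * A^(3/2)), dimensionless,
  maximal (1/(6*pi)) for a sphere;
* GLN = sum_i (sum_j R(i,j))^2 / sum_ij R(i,j) where R is the run-length
  matrix of maximal same-bin runs along the 13 unique 3D directions,
  discretized with a fixed bin width;
* wavelet GLN applies an undecimated single-level 3D separable wavelet
  transform, takes a configured sub-band (default HLH over the x, y, z
  axes) and computes GLN on the filtered values inside the region.

The run matrices can be merged over directions before GLN (default) or GLN
can be averaged over per-direction matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "DiscretizationConfig",
    "WaveletConfig",
    "DIRECTIONS_13",
    "discretize_fixed_bin_width",
    "run_length_matrix",
    "gln_from_matrix",
    "first_order_energy",
    "shape_compactness",
    "glrlm_gray_level_nonuniformity",
    "wavelet_subband",
    "wavelet_gln",
]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    # one representative per antiparallel pair; first nonzero component positive
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                first = next(c for c in d if c != 0)
                if first > 0:
                    dirs.append(d)
    assert len(dirs) == 13
    return tuple(dirs)


#: the 13 unique (up to sign) unit-offset directions of a 3D lattice
DIRECTIONS_13 = _unique_directions()


@dataclass
class DiscretizationConfig:
    """Gray-level discretization and run-matrix aggregation settings.

    ``bin_width`` is in HU (25 HU is common practice for CT); ``aggregation``
    is "merge" (sum run matrices over directions, then GLN) or "average"
    (GLN per direction, averaged).
    """

    bin_width: float = 25.0
    aggregation: str = "merge"
    directions: tuple[tuple[int, int, int], ...] = field(default=DIRECTIONS_13)

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive: {self.bin_width}")
        if self.aggregation not in ("merge", "average"):
            raise ValueError(f"aggregation must be 'merge' or 'average': {self.aggregation!r}")


@dataclass
class WaveletConfig:
    """Wavelet filter settings for the wavelet-GLN feature.

    ``subband`` is a 3-letter code over the (x, y, z) axes, 'L' = low-pass,
    'H' = high-pass; the default HLH follows the originating four-feature
    signature.  The transform is stationary (undecimated) so sub-band voxels
    align with the mask grid.
    """

    family: str = "coif1"
    subband: str = "HLH"
    level: int = 1

    def validate(self) -> None:
        if len(self.subband) != 3 or any(c not in "LH" for c in self.subband):
            raise ValueError(f"subband must be 3 letters over {{L,H}}: {self.subband!r}")
        if self.level != 1:
            raise ValueError("only a single decomposition level is supported")


def discretize_fixed_bin_width(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Map intensities to 1-based gray bins of fixed width anchored at min."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=np.int64)
    return np.floor((values - values.min()) / float(bin_width)).astype(np.int64) + 1


def run_length_matrix(
    bins: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]
) -> np.ndarray:
    """GLRLM for one direction: R[i-1, j-1] = count of runs of bin i, length j.

    A run is a maximal sequence of mask voxels with equal gray bin that are
    consecutive along ``direction``.  Voxels outside the mask break runs.
    """
    mask = np.asarray(mask).astype(bool)
    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.zeros((0, 0), dtype=np.int64)
    d = np.asarray(direction, dtype=np.int64)
    if not np.any(d):
        raise ValueError("direction must be nonzero")
    norm2 = int(d @ d)
    t = idx @ d  # position along the line, in steps of |d|^2 after scaling
    # integer line identifier: |d|^2 * idx - (idx.d) d is constant along a line
    key = idx * norm2 - t[:, None] * d[None, :]
    vals = np.asarray(bins)[tuple(idx.T)]
    order = np.lexsort((t, key[:, 2], key[:, 1], key[:, 0]))
    t_s, key_s, vals_s = t[order], key[order], vals[order]
    same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
    adjacent = (t_s[1:] - t_s[:-1]) == norm2
    same_bin = vals_s[1:] == vals_s[:-1]
    # a new run starts wherever continuity breaks
    breaks = np.flatnonzero(~(same_line & adjacent & same_bin)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(vals_s)]))
    lengths = ends - starts
    run_bins = vals_s[starts]
    n_levels = int(np.asarray(bins)[mask].max())
    mat = np.zeros((n_levels, int(lengths.max())), dtype=np.int64)
    np.add.at(mat, (run_bins - 1, lengths - 1), 1)
    return mat


def gln_from_matrix(mat: np.ndarray) -> float:
    """Gray-level nonuniformity of a run matrix: sum_i(row sum)^2 / N_runs."""
    total = mat.sum()
    if total == 0:
        return float("nan")
    row = mat.sum(axis=1).astype(float)
    return float(np.sum(row**2) / total)


def _pad_to_shape(mat: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=mat.dtype)
    out[: mat.shape[0], : mat.shape[1]] = mat
    return out


def glrlm_gray_level_nonuniformity(
    image: np.ndarray, mask: np.ndarray, disc: DiscretizationConfig | None = None
) -> float:
    """GLRLM gray-level nonuniformity of the masked region.

    Intensities are discretized with a fixed bin width over the mask; run
    matrices from the 13 directions are merged (or GLN is averaged per
    direction, per ``disc.aggregation``).  A region falling into a single
    gray bin degenerates to GLN = total run count, which is returned as-is.
    """
    disc = disc or DiscretizationConfig()
    disc.validate()
    mask = np.asarray(mask).astype(bool)
    if np.count_nonzero(mask) < 1:
        warnings.warn("GLN undefined on an empty mask")
        return float("nan")
    image = np.asarray(image, dtype=float)
    bins = np.zeros(image.shape, dtype=np.int64)
    bins[mask] = discretize_fixed_bin_width(image[mask], disc.bin_width)
    mats = [run_length_matrix(bins, mask, d) for d in disc.directions]
    if disc.aggregation == "merge":
        shape = (max(m.shape[0] for m in mats), max(m.shape[1] for m in mats))
        merged = sum(_pad_to_shape(m, shape) for m in mats)
        return gln_from_matrix(merged)
    return float(np.mean([gln_from_matrix(m) for m in mats]))


def first_order_energy(image: np.ndarray, mask: np.ndarray) -> float:
    """Sum of squared raw intensities (HU) over the mask; no intensity shift."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        warnings.warn("energy undefined on an empty mask")
        return float("nan")
    vals = np.asarray(image, dtype=float)[mask]
    return float(np.sum(vals**2))


def shape_compactness(mask: np.ndarray, spacing, surface_area_mm2: float | None = None) -> float:
    """Compactness (variant 1) of the mask: V / (sqrt(pi) * A^(3/2)).

    V is the voxel volume in mm^3 and A the marching-cubes surface area in
    mm^2 (shared with the SA/V biomarker).  Dimensionless and scale
    invariant; a sphere attains the maximum 1/(6*pi) ~= 0.0531.
    """
    from .qib import lesion_surface_area_mm2  # shared mesh; avoids an import cycle

    mask = np.asarray(mask).astype(bool)
    spacing = tuple(float(s) for s in spacing)
    volume_mm3 = float(np.count_nonzero(mask)) * float(np.prod(spacing))
    if volume_mm3 == 0:
        raise ValueError("compactness undefined: mask volume is zero")
    area = lesion_surface_area_mm2(mask, spacing) if surface_area_mm2 is None else surface_area_mm2
    if not np.isfinite(area) or area <= 0:
        raise ValueError(f"degenerate surface mesh (area {area}); cannot compute compactness")
    return float(volume_mm3 / (np.sqrt(np.pi) * area**1.5))


_LETTER = {"L": "a", "H": "d"}  # pywt: 'a' approximation (low-pass), 'd' detail


def wavelet_subband(image: np.ndarray, wcfg: WaveletConfig | None = None) -> np.ndarray:
    """Single-level stationary 3D wavelet sub-band, same shape as the input.

    Axis lengths are padded symmetrically at the end to even parity (the
    stationary transform requires it) and the result is cropped back.
    """
    wcfg = wcfg or WaveletConfig()
    wcfg.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("expected a 3D volume")
    wavelet = pywt.Wavelet(wcfg.family)
    if min(image.shape) < wavelet.dec_len:
        raise ValueError(
            f"volume {image.shape} too small for one {wcfg.family} decomposition level"
        )
    pad = [(0, s % 2) for s in image.shape]
    padded = np.pad(image, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    key = "".join(_LETTER[c] for c in wcfg.subband)
    band = coeffs[key]
    return band[: image.shape[0], : image.shape[1], : image.shape[2]]


def wavelet_gln(
    image: np.ndarray,
    mask: np.ndarray,
    wcfg: WaveletConfig | None = None,
    disc: DiscretizationConfig | None = None,
) -> float:
    """GLRLM gray-level nonuniformity computed on a wavelet sub-band.

    The transform is undecimated, so sub-band voxels align with the mask; the
    computation is restricted to the mask bounding box (padded by the filter
    support) for speed, which leaves the masked coefficients unchanged.
    """
    wcfg = wcfg or WaveletConfig()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        warnings.warn("wavelet GLN undefined on an empty mask")
        return float("nan")
    image = np.asarray(image, dtype=float)
    margin = 2 * pywt.Wavelet(wcfg.family).dec_len
    lo, hi = [], []
    for axis in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != axis))
        nz = np.flatnonzero(proj)
        lo.append(max(0, nz[0] - margin))
        hi.append(min(mask.shape[axis], nz[-1] + 1 + margin))
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    band = wavelet_subband(image[box], wcfg)
    return glrlm_gray_level_nonuniformity(band, mask[box], disc)
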