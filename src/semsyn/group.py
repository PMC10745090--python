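"""Group-level statistics and model-comparison indices.

Subject maps (ΔR, specificity, context contrasts ...) are smoothed with an
isotropic Gaussian kernel, tested against zero with a one-sided one-sample
t-test, and thresholded with Benjamini–Hochberg FDR control.  On top of the
thresholded maps, the module provides the comparison indices used to relate
semantic and syntactic sensitivity: top-decile peak regions, Jaccard
overlap, the log10 semantic/syntactic specificity index, unique
contributions of a feature space, synergy of joint (integral) features over
concatenation, context-length contrasts and per-hemisphere counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .encoding import EncodingResult
from .grids import GridError, VoxelGrid, VoxelMap, check_same_grid

__all__ = [
    "GroupResult", "SpecificityMap", "gaussian_smooth", "group_ttest",
    "fdr_correct", "group_analysis", "peak_regions", "jaccard",
    "specificity_index", "unique_contribution", "synergy",
    "context_contrast", "hemisphere_counts", "fwhm_to_sigma",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm_mm / FWHM_FACTOR


@dataclass
class GroupResult:
    """One-sample group test with FDR thresholding."""

    t: VoxelMap
    z: VoxelMap
    p: VoxelMap
    mask: np.ndarray
    z_fdr: float
    q: float


@dataclass
class SpecificityMap:
    """log10(r_semantic / r_syntactic) per voxel, valid where both > 0."""

    values: np.ndarray
    valid: np.ndarray
    grid: VoxelGrid


def gaussian_smooth(vmap: VoxelMap, fwhm_mm: float,
                    voxel_size_mm=(4.0, 4.0, 4.0)) -> VoxelMap:
    """Separable 3-D Gaussian smoothing on the voxel lattice.

    The kernel is renormalised within the voxel mask (as with a brain
    mask), so a constant map stays constant and no mass is drawn from
    positions outside the mask.
    """
    idx, shape = vmap.grid.lattice_indices(voxel_size_mm)
    size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_vox = fwhm_to_sigma(fwhm_mm) / size
    dense = np.zeros(shape)
    mask = np.zeros(shape)
    dense[tuple(idx.T)] = vmap.values
    mask[tuple(idx.T)] = 1.0
    num = ndimage.gaussian_filter(dense, sigma=sigma_vox, mode="constant", truncate=6.0)
    den = ndimage.gaussian_filter(mask, sigma=sigma_vox, mode="constant", truncate=6.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    out = sm[tuple(idx.T)]
    return VoxelMap(values=out, grid=vmap.grid, valid=vmap.valid.copy())


def group_ttest(maps: list[VoxelMap] | np.ndarray,
                grid: VoxelGrid | None = None) -> tuple[VoxelMap, VoxelMap, VoxelMap]:
    """One-sided one-sample t-test against zero, per voxel.

    Returns (t, z, p) maps; z is the standard-normal quantile of 1 - p.
    Zero-variance voxels are resolved by sign: positive mean -> p ~ 0,
    otherwise p = 1.
    """
    if isinstance(maps, np.ndarray):
        data = np.asarray(maps, dtype=float)
        if grid is None:
            raise ValueError("grid required when passing a raw subject × voxel array")
    else:
        if len(maps) == 0:
            raise ValueError("no subject maps given")
        grid = maps[0].grid
        for m in maps[1:]:
            check_same_grid(grid, m.grid)
        data = np.vstack([m.values for m in maps])
    n_sub = data.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects for a group test")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = sd < 1e-15
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n_sub))
    p = stats.t.sf(t, df=n_sub - 1)
    t[zero_var] = np.where(mean[zero_var] > 0, np.inf, 0.0)
    p[zero_var] = np.where(mean[zero_var] > 0, np.finfo(float).tiny, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    z = stats.norm.isf(p)
    return (VoxelMap(t, grid), VoxelMap(z, grid), VoxelMap(p, grid))


def fdr_correct(p: VoxelMap | np.ndarray, q: float = 0.005,
                z: VoxelMap | np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up at level q.

    Returns the rejection mask and z_FDR, the smallest z-score among
    rejected voxels (+inf when nothing is rejected).  When no z map is
    given, z is derived from p via the normal quantile.
    """
    pv = p.values if isinstance(p, VoxelMap) else np.asarray(p, dtype=float)
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    if z is None:
        zv = stats.norm.isf(np.clip(pv, np.finfo(float).tiny, 1.0))
    else:
        zv = z.values if isinstance(z, VoxelMap) else np.asarray(z, dtype=float)
    z_fdr = float(zv[reject].min()) if reject.any() else math.inf
    return reject, z_fdr


def group_analysis(subject_maps: np.ndarray, grid: VoxelGrid, *,
                   q: float = 0.005, fwhm_mm: float = 6.0,
                   voxel_size_mm=(4.0, 4.0, 4.0)) -> GroupResult:
    """Smooth subject maps, run the one-sided group t-test, FDR-threshold."""
    smoothed = np.vstack([
        gaussian_smooth(VoxelMap(row, grid), fwhm_mm, voxel_size_mm).values
        for row in np.asarray(subject_maps, dtype=float)
    ])
    t, z, p = group_ttest(smoothed, grid)
    mask, z_fdr = fdr_correct(p, q=q, z=z)
    return GroupResult(t=t, z=z, p=p, mask=mask, z_fdr=z_fdr, q=q)


def peak_regions(vmap: VoxelMap) -> set:
    """Voxels in the top decile of the map (|set| = ceil(0.10 n)).

    Ties are broken by voxel id so the result is stable.
    """
    n = vmap.grid.n_voxels
    if n == 0:
        raise ValueError("empty map")
    m = math.ceil(0.10 * n)
    order = np.lexsort((vmap.grid.voxel_ids, -vmap.values))
    return set(vmap.grid.voxel_ids[order[:m]].tolist())


def jaccard(a: set, b: set) -> float:
    """Intersection-over-union of two voxel sets: J = |A∩B| / |A∪B|."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def specificity_index(r_sem: VoxelMap, r_syn: VoxelMap) -> SpecificityMap:
    """x = log10(r_semantic / r_syntactic), defined where both inputs > 0.

    Positive x marks a voxel more sensitive to semantic features by a
    factor 10^x; negative x marks syntactic preference.  Voxels where either
    increase is nonpositive are masked invalid rather than erroring.
    """
    check_same_grid(r_sem.grid, r_syn.grid)
    valid = (r_sem.values > 0) & (r_syn.values > 0)
    values = np.full(r_sem.values.shape, np.nan)
    values[valid] = np.log10(r_sem.values[valid] / r_syn.values[valid])
    return SpecificityMap(values=values, valid=valid, grid=r_sem.grid)


def _compare_results(a: EncodingResult, b: EncodingResult) -> np.ndarray:
    if a.per_fold.shape != b.per_fold.shape:
        raise ValueError("encoding results have mismatched folds or voxel grids")
    return a.r_cv - b.r_cv


def unique_contribution(single: EncodingResult, concat: EncodingResult,
                        grid: VoxelGrid | None = None):
    """R(concatenated spaces) − R(single space): variance only the added
    space explains."""
    values = _compare_results(concat, single)
    return values if grid is None else VoxelMap(values, grid)


def synergy(integral: EncodingResult, concat: EncodingResult,
            grid: VoxelGrid | None = None):
    """R(integral features) − R(concatenated semantic+syntactic features).

    Positive synergy means jointly-coded features explain signal that no
    linear combination of the separate spaces captures.
    """
    values = _compare_results(integral, concat)
    return values if grid is None else VoxelMap(values, grid)


def context_contrast(larger_k: EncodingResult, smaller_k: EncodingResult,
                     grid: VoxelGrid | None = None):
    """ΔR between a longer-context and a shorter-context model."""
    values = _compare_results(larger_k, smaller_k)
    return values if grid is None else VoxelMap(values, grid)


def hemisphere_counts(mask: np.ndarray, grid: VoxelGrid) -> dict:
    """Significant-voxel counts per hemisphere and their right/left ratio."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != grid.n_voxels:
        raise ValueError("mask length does not match grid")
    hemi = np.asarray(grid.hemisphere)
    if not set(np.unique(hemi)) <= {"L", "R"}:
        raise ValueError("grid is missing L/R hemisphere labels")
    left = int(np.sum(mask & (hemi == "L")))
    right = int(np.sum(mask & (hemi == "R")))
    ratio = right / left if left > 0 else math.inf if right > 0 else math.nan
    return {"left": left, "right": right, "right_left_ratio": ratio}
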