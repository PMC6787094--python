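"""Voxelwise maps: sample entropy, intrinsic connectivity contrast (ICC),
map normalisation, Gaussian smoothing, and multi-map overlap.

Sample entropy (SampEn) quantifies signal unpredictability: the negative
log of the conditional probability that two sequences similar for m points
remain similar for m+1 points (similarity = Chebyshev distance within
r = r_factor * SD).  The ICC is a degree-like integration measure: the sum
over all other voxels of the squared Pearson correlation with each voxel's
timeseries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_preprocess import VolumeSeries


@dataclass(frozen=True)
class SampEnConfig:
    """Template length ``m`` and tolerance factor ``r_factor`` (x SD).

    Defaults m=3, r_factor=0.6 are the values identified as optimal for
    resting-state fMRI. ``closed_tolerance`` uses distance <= r (so a
    constant series scores exactly 0); ``population_sd`` selects the
    divide-by-T standard-deviation convention.
    """

    m: int = 3
    r_factor: float = 0.6
    closed_tolerance: bool = True
    population_sd: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with the raw template-match counts A (m+1) and B (m)."""

    value: float
    n_matches_m_plus_1: int
    n_matches_m: int

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class VoxelMap:
    """3D scalar field on a voxel grid, defined inside ``mask``."""

    data: np.ndarray
    mask: np.ndarray
    kind: str = "sampen"
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask grids differ")

    def values(self) -> np.ndarray:
        return self.data[self.mask]


def sample_entropy(series: np.ndarray, cfg: SampEnConfig = SampEnConfig()) -> SampEnResult:
    """SampEn = -log(A/B) over unordered template pairs.

    B counts pairs of length-m templates (start indices 0..T-m-1, the last
    length-m template dropped so the m and m+1 template sets align) whose
    Chebyshev distance is within r; A counts the same for length m+1.
    Self-matches are excluded.  Returns NaN (``is_defined`` False) when no
    matches exist at either length.
    """
    x = np.asarray(series, dtype=float).ravel()
    t = x.size
    m = cfg.m
    if t < m + 2:
        raise ValueError(f"series too short: length {t} < m+2 = {m + 2}")
    sd = x.std(ddof=0 if cfg.population_sd else 1)
    r = cfg.r_factor * sd

    n_templ = t - m  # templates usable at both lengths
    # Chebyshev distances via running elementwise max over lags
    b = _count_pairs(x, m, n_templ, r, cfg.closed_tolerance)
    a = _count_pairs(x, m + 1, n_templ, r, cfg.closed_tolerance)
    if a == 0 or b == 0:
        return SampEnResult(value=float("nan"), n_matches_m_plus_1=a, n_matches_m=b)
    return SampEnResult(value=-math.log(a / b), n_matches_m_plus_1=a, n_matches_m=b)


def _count_pairs(x: np.ndarray, length: int, n_templ: int, r: float, closed: bool) -> int:
    """Number of unordered template pairs within Chebyshev distance r."""
    # templates start at 0..n_templ-1; template k spans x[k:k+length]
    templ = np.lib.stride_tricks.sliding_window_view(x, length)[:n_templ]
    d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
    hit = (d <= r) if closed else (d < r)
    return int((np.triu(hit, k=1)).sum())


def sampen_map(vol: VolumeSeries, cfg: SampEnConfig = SampEnConfig()) -> VoxelMap:
    """Per-voxel SampEn inside the mask.

    Voxels whose SampEn is undefined (no template matches) are dropped
    from the output mask with a warning.
    """
    if not vol.mask.any():
        raise ValueError("empty mask")
    out = np.zeros(vol.data.shape[:3])
    new_mask = vol.mask.copy()
    idx = np.argwhere(vol.mask)
    n_undef = 0
    for i, j, k in idx:
        res = sample_entropy(vol.data[i, j, k], cfg)
        if res.is_defined:
            out[i, j, k] = res.value
        else:
            new_mask[i, j, k] = False
            n_undef += 1
    if n_undef:
        warnings.warn(f"{n_undef} voxels had undefined SampEn and were masked out")
    return VoxelMap(data=out, mask=new_mask, kind="sampen", voxel_size_mm=vol.voxel_size_mm)


def icc_map(vol: VolumeSeries) -> VoxelMap:
    """Raw intrinsic connectivity contrast: ICC(i) = sum_{j != i} r_ij^2."""
    idx = np.argwhere(vol.mask)
    if idx.shape[0] < 2:
        raise ValueError("need at least 2 in-mask voxels")
    series = vol.data[vol.mask]  # V x T
    var = series.var(axis=1)
    good = var > 0
    if not good.all():
        warnings.warn(f"{int((~good).sum())} zero-variance voxels excluded from ICC")
    series = series[good]
    idx = idx[good]
    if series.shape[0] < 2:
        raise ValueError("fewer than 2 nonconstant in-mask voxels")
    r = np.corrcoef(series)
    icc = (r**2).sum(axis=1) - 1.0  # subtract the self-correlation r_ii^2 = 1
    out = np.zeros(vol.data.shape[:3])
    mask = np.zeros(vol.data.shape[:3], dtype=bool)
    out[tuple(idx.T)] = icc
    mask[tuple(idx.T)] = True
    return VoxelMap(data=out, mask=mask, kind="icc_raw", voxel_size_mm=vol.voxel_size_mm)


def normalize_zscore_map(vmap: VoxelMap) -> VoxelMap:
    """Z-score the map over its mask (population SD); constant maps -> zeros."""
    vals = vmap.values()
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = vals.std(ddof=0)
    out = np.zeros_like(vmap.data)
    if sd > 0:
        out[vmap.mask] = (vals - vals.mean()) / sd
    kind = "icc_norm" if vmap.kind.startswith("icc") else vmap.kind
    return replace(vmap, data=out, kind=kind)


def smooth_map_gaussian(vmap: VoxelMap, fwhm_mm: float) -> VoxelMap:
    """Mask-aware 3D Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)).

    The map is smoothed as (G * masked map) / (G * mask) so voxels near
    the mask edge are not dimmed by out-of-mask zeros.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be positive")
    if fwhm_mm == 0:
        return replace(vmap, data=vmap.data.copy())
    sigma_vox = [
        fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v for v in vmap.voxel_size_mm
    ]
    masked = np.where(vmap.mask, vmap.data, 0.0)
    num = ndimage.gaussian_filter(masked, sigma=sigma_vox)
    den = ndimage.gaussian_filter(vmap.mask.astype(float), sigma=sigma_vox)
    out = np.zeros_like(vmap.data)
    inside = vmap.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return replace(vmap, data=out)


def binarize_and_overlap(maps: list[VoxelMap], thresholds: list[float]) -> VoxelMap:
    """Binarise each map at its threshold (value >= threshold, in-mask) and
    intersect across maps; used to find regions jointly significant in
    several contrast maps."""
    if len(maps) != len(thresholds):
        raise ValueError("one threshold per map required")
    if not maps:
        raise ValueError("no maps given")
    grid = maps[0].data.shape
    overlap = np.ones(grid, dtype=bool)
    for vmap, thr in zip(maps, thresholds):
        if vmap.data.shape != grid:
            raise ValueError("maps do not share a voxel grid")
        overlap &= vmap.mask & (vmap.data >= thr)
    return VoxelMap(
        data=overlap.astype(float),
        mask=overlap,
        kind="mask",
        voxel_size_mm=maps[0].voxel_size_mm,
    )
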