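"""Static and dynamic (tapered sliding-window) functional connectivity.

Static FC is the Pearson correlation between regional timecourses over the
whole scan.  Dynamic FC uses a tapered window built by convolving a 22-TR
rectangle with a 3-TR Gaussian, sliding in 1-TR steps; each window yields a
weighted Pearson correlation matrix, giving W = T - 23 + 1 windows under
the defaults (229 windows for T=251, 273 for T=295).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import RoiTimeseries, VolumeSeries

PROVENANCES = (
    "static",
    "window",
    "centroid_integrated",
    "centroid_segregated",
    "mean_difference",
    "common_difference",
)


@dataclass
class FCMatrix:
    """N x N symmetric signed connectivity matrix."""

    weights: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    provenance: str = "static"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.region_ids:
            self.region_ids = [f"roi{i:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class TaperWindow:
    """Normalised taper weights for windowed correlation."""

    weights: np.ndarray
    rect_length_tr: int = 22
    gaussian_sigma_tr: float = 3.0
    step_tr: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("taper weights must be nonnegative")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("taper weights must sum to 1")

    @property
    def length(self) -> int:
        return self.weights.size


@dataclass
class DynamicFCSeries:
    """Ordered sequence of windowed FC matrices."""

    matrices: list[FCMatrix]
    window_starts: np.ndarray
    taper: TaperWindow

    @property
    def n_windows(self) -> int:
        return len(self.matrices)

    def stacked(self) -> np.ndarray:
        """W x N x N array of window weights."""
        return np.stack([m.weights for m in self.matrices])


def static_fc(ts: RoiTimeseries) -> FCMatrix:
    """Whole-scan Pearson correlation matrix."""
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.region_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant region timecourse(s): {bad}")
    w = np.corrcoef(ts.data.T)
    np.fill_diagonal(w, 1.0)
    return FCMatrix(weights=(w + w.T) / 2.0, region_ids=list(ts.region_ids), provenance="static")


def build_taper(rect_length: int = 22, sigma: float = 3.0, step: int = 1) -> TaperWindow:
    """Rectangle-convolved-with-Gaussian taper, cropped to rect_length + 1 taps.

    The Gaussian is sampled at half-integer offsets (an even-length symmetric
    kernel), so convolving with the even-length rectangle gives an odd-length
    symmetric taper that can be cropped symmetrically to L_w = rect_length + 1
    taps and renormalised.  A degenerate (sigma -> 0) Gaussian returns the
    bare rectangle of length rect_length.
    """
    if rect_length < 2:
        raise ValueError("rect_length must be >= 2")
    if sigma < 0:
        raise ValueError("sigma must be positive")
    if sigma < 1e-8:  # degenerate Gaussian: pure rectangle
        w = np.full(rect_length, 1.0 / rect_length)
        return TaperWindow(weights=w, rect_length_tr=rect_length, gaussian_sigma_tr=sigma, step_tr=step)
    radius = max(1, int(np.ceil(4 * sigma)))
    offsets = np.arange(-radius, radius) + 0.5  # half-integer sampling, even length
    gauss = np.exp(-(offsets**2) / (2.0 * sigma**2))
    gauss /= gauss.sum()
    rect = np.ones(rect_length)
    full = np.convolve(rect, gauss)  # odd length: rect_length + 2*radius - 1
    target = rect_length + 1
    excess = full.size - target
    if excess < 0:
        raise ValueError("sigma too large for the requested rectangle")
    lo = excess // 2
    w = full[lo : lo + target]
    w = w / w.sum()
    return TaperWindow(weights=w, rect_length_tr=rect_length, gaussian_sigma_tr=sigma, step_tr=step)


def weighted_correlation(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation across rows of the L x N block ``x``."""
    w = w / w.sum()
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    if np.any(var <= 0):
        raise ValueError("zero weighted variance in a region within a window")
    denom = np.sqrt(np.outer(var, var))
    corr = cov / denom
    np.fill_diagonal(corr, 1.0)
    return np.clip((corr + corr.T) / 2.0, -1.0, 1.0)


def dynamic_fc(ts: RoiTimeseries, taper: TaperWindow | None = None) -> DynamicFCSeries:
    """Sliding tapered-window FC: one weighted correlation matrix per window."""
    if taper is None:
        taper = build_taper()
    lw = taper.length
    t = ts.n_timepoints
    if t < lw + 1:
        raise ValueError(f"need at least {lw + 1} timepoints for dynamic FC, got {t}")
    step = taper.step_tr
    starts = np.arange(0, t - lw + 1, step)
    mats = []
    for s in starts:
        corr = weighted_correlation(ts.data[s : s + lw], taper.weights)
        mats.append(FCMatrix(weights=corr, region_ids=list(ts.region_ids), provenance="window"))
    return DynamicFCSeries(matrices=mats, window_starts=starts, taper=taper)


def seed_correlation_map(ts_or_vol, seed):
    """Pearson correlation of every region/voxel with a seed timecourse.

    For ROI input, ``seed`` is a region label and the result is a vector of
    correlations (the seed's column of the static FC matrix).  For volume
    input, ``seed`` is a boolean voxel mask whose mean timecourse is
    correlated with every in-mask voxel, returning a VoxelMap.
    """
    from .voxel_metrics import VoxelMap

    if isinstance(ts_or_vol, RoiTimeseries):
        ts = ts_or_vol
        if seed not in ts.region_ids:
            raise ValueError(f"seed region {seed!r} not found")
        j = ts.region_ids.index(seed)
        seed_series = ts.data[:, j]
        if seed_series.std() == 0:
            raise ValueError("seed series is constant")
        return _corr_with(ts.data, seed_series)
    vol: VolumeSeries = ts_or_vol
    seed = np.asarray(seed, dtype=bool)
    if not seed.any():
        raise ValueError("empty seed mask")
    seed_series = vol.data[seed].mean(axis=0)
    if seed_series.std() == 0:
        raise ValueError("seed series is constant")
    flat = vol.data[vol.mask]
    r = _corr_with(flat.T, seed_series)
    out = np.zeros(vol.data.shape[:3])
    out[vol.mask] = r
    return VoxelMap(data=out, mask=vol.mask.copy(), kind="sampen", voxel_size_mm=vol.voxel_size_mm)


def _corr_with(data: np.ndarray, seed_series: np.ndarray) -> np.ndarray:
    xc = data - data.mean(axis=0)
    sc = seed_series - seed_series.mean()
    num = xc.T @ sc
    den = np.sqrt((xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r
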