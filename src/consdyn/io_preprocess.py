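"""Input/output and timeseries denoising.

Reads region-of-interest (ROI) BOLD timeseries tables, parcellates 4D
volumetric series with an integer-labelled atlas, and applies the purely
computational denoising steps: optional hyperbolic-tangent despiking,
joint confound + linear-trend regression, and zero-phase band-pass
filtering (default 0.008--0.09 Hz, the standard resting-state band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class RoiTimeseries:
    """T x N matrix of regional signals with sampling interval ``tr_seconds``."""

    data: np.ndarray
    tr_seconds: float
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        t, n = self.data.shape
        if t < 2:
            raise ValueError("fewer than 2 timepoints")
        if n < 1:
            raise ValueError("no regions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains missing or non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.region_ids:
            self.region_ids = [f"roi{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError("region_ids length must match number of columns")
        if len(set(self.region_ids)) != n:
            raise ValueError("region_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class VolumeSeries:
    """X x Y x Z x T voxel array with a boolean brain mask."""

    data: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be X x Y x Z x T")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid must match data grid")
        if self.data.shape[3] < 2:
            raise ValueError("fewer than 2 timepoints")
        if not self.mask.any():
            raise ValueError("mask has no true voxels")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")


@dataclass
class ConfoundTable:
    """T x K nuisance regressors (motion parameters, noise components, ...)."""

    data: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if not np.all(np.isfinite(self.data)):
            raise ValueError("confound columns must be finite")
        if not self.names:
            self.names = [f"conf{i}" for i in range(self.data.shape[1])]
        if len(self.names) != self.data.shape[1]:
            raise ValueError("names length must match number of columns")


def read_roi_timeseries(
    path,
    tr_seconds: float,
    drop_initial_volumes: int = 0,
    subject_id: str = "",
    condition: str = "",
) -> RoiTimeseries:
    """Read a tab-separated timepoints-by-regions table.

    The file must have a header row of region labels and one row per TR.
    ``drop_initial_volumes`` discards that many leading scans (dummy volumes
    acquired before magnetisation equilibrium); the pipeline default is 5.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except FileNotFoundError:
        raise FileNotFoundError(f"timeseries file not found: {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric entry at row {row}, column {col!r}"
            )
    data = df.to_numpy(dtype=float)
    if np.isnan(data).any():
        i, j = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"missing value at row {i}, column {df.columns[j]!r}")
    if drop_initial_volumes:
        data = data[drop_initial_volumes:]
    if data.shape[0] < 2:
        raise ValueError("fewer than 2 timepoints")
    return RoiTimeseries(
        data=data,
        tr_seconds=tr_seconds,
        region_ids=[str(c) for c in df.columns],
        subject_id=subject_id,
        condition=condition,
    )


def write_roi_timeseries(ts: RoiTimeseries, path) -> None:
    """Write a RoiTimeseries back to TSV (full float precision round-trip)."""
    df = pd.DataFrame(ts.data, columns=ts.region_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_volume_series(path, mask_path=None, tr_seconds: float | None = None) -> VolumeSeries:
    """Load a 4D NIfTI-1 series (and optional 3D mask) into a VolumeSeries.

    Voxel sizes come from the affine; TR from the header unless overridden.
    Without a mask file, every voxel is in-mask.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return VolumeSeries(
        data=data,
        mask=mask,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_seconds=tr_seconds,
    )


def read_atlas_volume(path) -> np.ndarray:
    """Load an integer-coded 3D atlas volume (0 = background)."""
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D atlas, got shape {arr.shape}")
    return np.rint(arr).astype(int)


def write_voxel_map_nifti(vmap, path) -> None:
    """Write a VoxelMap as NIfTI-1 with the voxel sizes on the diagonal."""
    affine = np.diag([*vmap.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.where(vmap.mask, vmap.data, 0.0), affine), str(path))


def read_confounds(path) -> ConfoundTable:
    df = pd.read_csv(path, sep="\t")
    return ConfoundTable(data=df.to_numpy(dtype=float), names=[str(c) for c in df.columns])


def parcellate_volume(vol: VolumeSeries, atlas: np.ndarray) -> RoiTimeseries:
    """Average voxel timecourses within each atlas parcel.

    ``atlas`` is an integer label volume on the same grid as ``vol``;
    0 marks background.  One output column per distinct nonzero label,
    ascending label order, each the unweighted mean over that parcel's
    in-mask voxels.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != vol.data.shape[:3]:
        raise ValueError("atlas grid must match volume grid")
    labels = np.unique(atlas[atlas > 0])
    if labels.size == 0:
        raise ValueError("atlas contains no nonzero labels")
    cols, kept = [], []
    for lab in labels:
        sel = (atlas == lab) & vol.mask
        if not sel.any():
            warnings.warn(f"parcel {lab} has no in-mask voxels; column dropped")
            continue
        cols.append(vol.data[sel].mean(axis=0))
        kept.append(int(lab))
    if not cols:
        raise ValueError("no parcel has in-mask voxels")
    return RoiTimeseries(
        data=np.column_stack(cols),
        tr_seconds=vol.tr_seconds,
        region_ids=[str(k) for k in kept],
    )


def tanh_despike(data: np.ndarray, mad_factor: float = 4.0) -> np.ndarray:
    """Squash spikes with ``x -> c * tanh(x / c)`` around each series' median.

    ``c`` is ``mad_factor`` times the median absolute deviation of the
    demeaned series, so values within a few MADs pass nearly unchanged
    while extreme excursions saturate.  Scale-free by construction.
    """
    data = np.asarray(data, dtype=float)
    med = np.median(data, axis=0, keepdims=True)
    centred = data - med
    mad = np.median(np.abs(centred), axis=0, keepdims=True)
    c = mad_factor * mad
    safe_c = np.where(c > 0, c, 1.0)
    out = np.where(c > 0, safe_c * np.tanh(centred / safe_c), centred)
    return out + med


def _trend_design(t: int, confounds: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(t), np.linspace(-1.0, 1.0, t)]
    if confounds is not None and confounds.size:
        cols.extend(np.asarray(confounds, dtype=float).T)
    return np.column_stack(cols)


def _regress_out(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    # rank-deficient designs (collinear confounds) handled by lstsq; warn
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("confound design is rank-deficient; collinear columns effectively dropped")
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def denoise_timeseries(
    ts,
    confounds: ConfoundTable | None = None,
    band_hz: tuple[float, float] = (0.008, 0.09),
    despike: bool = False,
    filter_order: int = 4,
):
    """Denoise a :class:`RoiTimeseries` or :class:`VolumeSeries`.

    Steps, in order: (1) optional tanh despike; (2) one joint ordinary
    least-squares regression removing an intercept, a linear trend and any
    confound columns; (3) zero-phase Butterworth band-pass inside
    ``band_hz``; (4) residual mean/trend re-projection so the output is
    numerically trend-free.
    """
    is_vol = isinstance(ts, VolumeSeries)
    if is_vol:
        t_len = ts.data.shape[3]
        flat = ts.data[ts.mask].T  # T x V
    else:
        t_len = ts.data.shape[0]
        flat = ts.data.copy()
    tr = ts.tr_seconds
    nyq = 1.0 / (2.0 * tr)
    low, high = band_hz
    if not (0 <= low < high < nyq):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyq:g}) Hz")
    if confounds is not None and confounds.data.shape[0] != t_len:
        raise ValueError("confound table length does not match timeseries")

    if despike:
        flat = tanh_despike(flat)
    design = _trend_design(t_len, None if confounds is None else confounds.data)
    flat = _regress_out(flat, design)

    if low > 0:
        sos = signal.butter(filter_order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    else:
        sos = signal.butter(filter_order, high, btype="lowpass", fs=1.0 / tr, output="sos")
    flat = signal.sosfiltfilt(sos, flat, axis=0)
    # filtering can reintroduce a tiny mean/trend at the edges; project out
    flat = _regress_out(flat, _trend_design(t_len, None))

    if is_vol:
        out = np.zeros_like(ts.data)
        out[ts.mask] = flat.T
        return replace(ts, data=out)
    return replace(ts, data=flat)


def extract_noise_components(noise_ts: np.ndarray, k: int) -> ConfoundTable:
    """First ``k`` principal-component score timecourses of a noise matrix.

    Used for aCompCor-style confounds: the T x V matrix of noise-tissue
    voxel signals is column-demeaned, and the top-k left singular vectors
    (unit norm, ordered by decreasing explained variance) are returned.
    """
    x = np.asarray(noise_ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("noise matrix must be T x V")
    t, v = x.shape
    if k > min(t, v):
        raise ValueError(f"k={k} exceeds min(T, V)={min(t, v)}")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    comps = u[:, :k]
    return ConfoundTable(data=comps, names=[f"noise_pc{i + 1}" for i in range(k)])
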