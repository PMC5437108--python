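"""Signal-level fMRI preprocessing and voxel-wise network measures.

Operates on 4D BOLD-like arrays on a shared grid: volume discarding, motion
exclusion, spatial smoothing, detrend + band-pass, nuisance regression,
mfALFF, pairwise functional connectivity, degree centrality, within-mask
z-standardization, peak-seed extraction, seed FC z-maps, and voxel-wise
map-behavior correlation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateInputError,
    InsufficientDataError,
)
__all__ = [
    "Volume",
    "BoldSeries",
    "Seed",
    "DegreeMap",
    "FWHM_TO_SIGMA",
    "discard_initial_volumes",
    "motion_exclude",
    "gaussian_smooth",
    "detrend_bandpass",
    "nuisance_regress",
    "mfalff_map",
    "fc_matrix",
    "degree_map",
    "z_standardize",
    "seed_from_peak",
    "seed_fc_zmap",
    "map_behavior_correlation",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """3D scalar grid with a voxel-to-mm affine (RAS+)."""

    data: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class BoldSeries:
    """4D (x, y, z, t) series with its repetition time in seconds."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    band_hz: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldSeries data must be 4D (x, y, z, t)")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class Seed:
    """Spherical seed: mm center, radius, and member voxel indices."""

    center_mm: tuple
    radius_mm: float
    voxels: tuple  # tuple of (i, j, k) voxel indices

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        for v in self.voxels:
            m[tuple(v)] = True
        return m


@dataclass
class DegreeMap:
    data: Volume
    r_threshold: float
    mask: np.ndarray


def discard_initial_volumes(bold: BoldSeries, k: int = 10) -> BoldSeries:
    """Drop the first k frames; TR is unchanged."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if bold.n_volumes <= k:
        raise InsufficientDataError(
            f"cannot discard {k} of {bold.n_volumes} volumes"
        )
    return BoldSeries(
        data=bold.data[..., k:], tr_s=bold.tr_s, affine=bold.affine,
        band_hz=bold.band_hz,
    )


def motion_exclude(
    motion: Sequence[float],
    trans_limit_mm: float = 2.5,
    rot_limit_deg: float = 2.5,
) -> bool:
    """Return True (keep) unless any max |translation| or |rotation| exceeds
    its limit. Strict >: values exactly at the limit are kept."""
    m = np.abs(np.asarray(motion, dtype=float))
    if m.shape != (6,):
        raise ValueError("motion must be a 6-vector (3 trans mm, 3 rot deg)")
    return not (np.any(m[:3] > trans_limit_mm) or np.any(m[3:] > rot_limit_deg))


def gaussian_smooth(
    data: np.ndarray, fwhm_mm: float, voxel_mm: Sequence[float]
) -> np.ndarray:
    """Separable Gaussian smoothing; sigma per axis = fwhm/(2 sqrt(2 ln 2))
    in mm, divided by the voxel size. 4D inputs are smoothed frame-wise."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.array(data, copy=True)
    vox = np.asarray(voxel_mm, dtype=float)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma=sigma_vox)
    if arr.ndim == 4:
        return ndimage.gaussian_filter(arr, sigma=(*sigma_vox, 0.0))
    raise ValueError("expected 3D or 4D data")


def detrend_bandpass(
    bold: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.10
) -> BoldSeries:
    """Per-voxel linear detrend, then an ideal frequency-domain band-pass
    retaining [low_hz, high_hz] (inclusive). The DC bin is always removed."""
    nyquist = 0.5 / bold.tr_s
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) invalid for Nyquist {nyquist}"
        )
    x = np.asarray(bold.data, dtype=float)
    t = x.shape[-1]
    # linear detrend (least squares on [1, time])
    tt = np.arange(t, dtype=float)
    design = np.column_stack([np.ones(t), tt])
    flat = x.reshape(-1, t)
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    detrended = flat - (design @ beta).T
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spec = np.fft.rfft(detrended, axis=-1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=-1).reshape(x.shape)
    return BoldSeries(
        data=out, tr_s=bold.tr_s, affine=bold.affine,
        band_hz=(low_hz, high_hz),
    )


def nuisance_regress(
    bold: BoldSeries, confounds: np.ndarray | None
) -> BoldSeries:
    """Regress confound time series (plus intercept) out of every voxel.

    Residuals are orthogonal to every confound column. Empty confounds
    reduce to mean centering.
    """
    x = np.asarray(bold.data, dtype=float)
    t = x.shape[-1]
    if confounds is None or np.size(confounds) == 0:
        design = np.ones((t, 1))
    else:
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != t:
            raise ValueError("confounds must have one row per frame")
        if c.shape[1] >= t:
            raise InsufficientDataError("more confounds than frames")
        design = np.column_stack([np.ones(t), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("confound design is rank deficient")
    flat = x.reshape(-1, t).T  # t x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return BoldSeries(
        data=resid.T.reshape(x.shape), tr_s=bold.tr_s, affine=bold.affine,
        band_hz=bold.band_hz,
    )


def mfalff_map(
    bold: BoldSeries,
    mask: np.ndarray,
    band_hz: tuple = (0.01, 0.10),
) -> np.ndarray:
    """Fractional low-frequency amplitude per voxel, normalized so the map
    mean within the mask is 1.

    fALFF = (sum of the amplitude spectrum inside the band) / (sum over all
    positive frequencies); the 'm' step divides by the within-mask mean.
    """
    low, high = band_hz
    x = np.asarray(bold.data, dtype=float)
    t = x.shape[-1]
    freqs = np.fft.rfftfreq(t, d=bold.tr_s)
    amp = np.abs(np.fft.rfft(x, axis=-1))
    pos = freqs > 0
    inband = (freqs >= low) & (freqs <= high) & pos
    total = amp[..., pos].sum(axis=-1)
    if np.all(total[mask] == 0):
        raise DegenerateInputError("zero spectrum everywhere in mask")
    with np.errstate(invalid="ignore", divide="ignore"):
        falff = np.where(total > 0, amp[..., inband].sum(axis=-1) / total, 0.0)
    mean_in_mask = falff[mask].mean()
    if mean_in_mask == 0:
        raise DegenerateInputError("mask-mean fALFF is zero")
    return falff / mean_in_mask


def fc_matrix(bold: BoldSeries, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r between the time series of all mask voxels.

    Returns (r, valid): r is V x V, symmetric with unit diagonal; rows and
    columns of constant voxels are NaN and valid marks usable voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    series = np.asarray(bold.data, dtype=float)[mask]  # V x t
    if series.shape[-1] < 3:
        raise InsufficientDataError("fc_matrix needs >= 3 frames")
    sd = series.std(axis=-1)
    # relative tolerance: a constant nonzero series has std ~ eps * |mean|
    valid = sd > 1e-12 * np.maximum(1.0, np.abs(series).max(axis=-1))
    centered = series - series.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1)
    safe = np.where(valid, norms, 1.0)
    unit = centered / safe[:, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    r[~valid, :] = np.nan
    r[:, ~valid] = np.nan
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    return r, valid


def degree_map(
    fc: np.ndarray, r_threshold: float = 0.10, weighted: bool = False
) -> np.ndarray:
    """Per-voxel count of off-diagonal connections with r strictly above the
    threshold. NaN entries (degenerate voxels) are never counted. With
    ``weighted=True`` the suprathreshold r values are summed instead."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("fc must be square")
    off = ~np.eye(fc.shape[0], dtype=bool)
    over = (fc > r_threshold) & off & np.isfinite(fc)
    if weighted:
        return np.where(over, fc, 0.0).sum(axis=1)
    return over.sum(axis=1).astype(float)


def z_standardize(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize within the mask to mean 0, sample sd 1; outside is 0."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(data, dtype=float)[mask]
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 mask voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant map within mask")
    out = np.zeros(np.shape(data), dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


def seed_from_peak(
    stat_map: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    radius_mm: float = 3.0,
    peak_mask: np.ndarray | None = None,
) -> Seed:
    """Sphere seed centered on the max-|stat| voxel.

    The peak is searched in ``peak_mask`` (defaults to ``mask``); membership
    is by center-to-center distance <= radius, intersected with ``mask``.
    """
    mask = np.asarray(mask, dtype=bool)
    pm = mask if peak_mask is None else (np.asarray(peak_mask, dtype=bool) & mask)
    if not pm.any():
        raise DegenerateInputError("empty peak-search mask")
    stat = np.asarray(stat_map, dtype=float)
    absstat = np.where(pm, np.abs(stat), -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(absstat)), stat.shape)
    affine = np.asarray(affine, dtype=float)
    center_mm = affine @ np.array([*peak_idx, 1.0])

    idx = np.argwhere(np.ones(stat.shape, dtype=bool))
    coords = (affine @ np.column_stack([idx, np.ones(len(idx))]).T).T[:, :3]
    dist = np.linalg.norm(coords - center_mm[:3], axis=1)
    members = [
        tuple(int(c) for c in idx[i])
        for i in np.nonzero(dist <= radius_mm + 1e-9)[0]
        if mask[tuple(idx[i])]
    ]
    if not members:
        raise DegenerateInputError("seed is empty after masking")
    return Seed(
        center_mm=tuple(float(v) for v in center_mm[:3]),
        radius_mm=float(radius_mm),
        voxels=tuple(members),
    )


def seed_fc_zmap(
    bold: BoldSeries, seed: Seed, mask: np.ndarray
) -> np.ndarray:
    """Fisher-z map of the correlation between the mean seed series and every
    remaining mask voxel. Seed voxels and saturated (|r| = 1) or degenerate
    voxels are NaN."""
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(bold.data, dtype=float)
    seed_mask = seed.mask(x.shape[:3])
    ts = x[seed_mask].mean(axis=0)
    if ts.std() == 0:
        raise DegenerateInputError("constant seed time series")
    out = np.full(x.shape[:3], np.nan)
    targets = mask & ~seed_mask
    series = x[targets]
    sd = series.std(axis=-1)
    nondegenerate = sd > 1e-12 * np.maximum(1.0, np.abs(series).max(axis=-1))
    centered = series - series.mean(axis=-1, keepdims=True)
    tc = ts - ts.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ tc) / (
            np.linalg.norm(centered, axis=-1) * np.linalg.norm(tc)
        )
    r = np.where(nondegenerate, r, np.nan)
    r = np.where(np.abs(r) >= 1.0 - 1e-12, np.nan, r)  # saturated: excluded
    out[targets] = np.arctanh(r)
    return out


def map_behavior_correlation(
    maps: np.ndarray,
    scores: Sequence[float],
    mask: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Voxel-wise Pearson (or partial) correlation between per-observation
    map values and behavior scores.

    ``maps`` is observations x (grid). Voxels that are NaN in any
    observation, or constant across observations, come back NaN. Returns
    (r_map, df).
    """
    maps = np.asarray(maps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = maps.shape[0]
    if scores.shape != (n,):
        raise ValueError("scores must match the number of observations")
    if n < 4:
        raise InsufficientDataError("need >= 4 observations")
    mask = np.asarray(mask, dtype=bool)
    vals = maps[:, mask]  # n x V
    finite = np.all(np.isfinite(vals), axis=0)
    sub = vals[:, finite]
    q = 0
    y = scores
    if covariates is not None and np.size(covariates) > 0:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        q = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise CollinearityError("covariate design is rank deficient")
        hat = design @ np.linalg.pinv(design)
        y = scores - hat @ scores
        sub = sub - hat @ sub
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    if ny == 0:
        raise DegenerateInputError("constant scores")
    vc = sub - sub.mean(axis=0)
    norms = np.linalg.norm(vc, axis=0)
    r_sub = np.full(sub.shape[1], np.nan)
    ok = norms > 0
    r_sub[ok] = np.clip((vc[:, ok].T @ yc) / (norms[ok] * ny), -1.0, 1.0)
    r = np.full(vals.shape[1], np.nan)
    r[finite] = r_sub
    out = np.full(mask.shape, np.nan)
    out[mask] = r
    return out, n - 2 - q


def r_threshold_for_p(p: float, df: int) -> float:
    """|r| giving a two-sided p at the stated df (inverse of the r->t map)."""
    tcrit = sps.t.isf(p / 2.0, df)
    return float(np.sqrt(tcrit ** 2 / (tcrit ** 2 + df)))
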