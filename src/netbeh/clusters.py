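"""Voxel-wise group statistics and Monte-Carlo cluster-extent inference.

Two-sample t maps with residuals, residual-based smoothness (FWHM)
estimation, a seedable Monte-Carlo estimate of the minimum cluster size
controlling family-wise error at a given voxel threshold, and connected
component extraction with peak reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import DegenerateInputError, InsufficientDataError
from .fmri import FWHM_TO_SIGMA

__all__ = [
    "SmoothnessEstimate",
    "AlphaSimResult",
    "Cluster",
    "ClusterTable",
    "group_t_map",
    "estimate_fwhm",
    "alphasim_min_cluster",
    "extract_clusters",
    "connectivity_structure",
]


@dataclass(frozen=True)
class SmoothnessEstimate:
    fwhm_mm: tuple  # per-axis FWHM in mm; NaN where unresolvable
    method: str = "residual-first-differences"

    @property
    def mean_fwhm_mm(self) -> float:
        vals = [v for v in self.fwhm_mm if np.isfinite(v)]
        if not vals:
            raise DegenerateInputError("no resolvable smoothness axis")
        return float(np.mean(vals))


@dataclass
class AlphaSimResult:
    voxel_p: float
    alpha: float
    min_cluster_voxels: int
    n_iterations: int
    connectivity: int
    fwhm_mm: float
    null_max_sizes: np.ndarray

    def fwer(self, k: int) -> float:
        """Empirical P(max null cluster size >= k)."""
        return float(np.mean(self.null_max_sizes >= k))

    def to_dict(self) -> dict:
        return {
            "voxel_p": self.voxel_p,
            "alpha": self.alpha,
            "min_cluster_voxels": int(self.min_cluster_voxels),
            "n_iterations": int(self.n_iterations),
            "connectivity": int(self.connectivity),
            "fwhm_mm": float(self.fwhm_mm),
            "null_max_sizes": [int(v) for v in self.null_max_sizes],
        }


@dataclass(frozen=True)
class Cluster:
    label: int
    size_voxels: int
    size_mm3: float
    peak_voxel: tuple
    peak_mm: tuple
    peak_stat: float


@dataclass
class ClusterTable:
    clusters: list
    labels: np.ndarray  # int label image, 0 = background

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def mask(self) -> np.ndarray:
        return self.labels > 0


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6-, 18-, or 26-neighbor connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def group_t_map(
    group_a: np.ndarray,
    group_b: np.ndarray,
    mask: np.ndarray,
    variant: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise two-sample t map (A minus B) plus residual volumes.

    ``group_a`` / ``group_b`` are subjects x (grid). Residuals are the
    per-subject deviations from their group's voxel mean, stacked A then B,
    for downstream smoothness estimation. Voxels with zero variance in both
    groups are NaN in the t map.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InsufficientDataError("need >= 2 subjects per group")
    mask = np.asarray(mask, dtype=bool)
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "pooled":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        elif variant == "welch":
            denom = np.sqrt(va / na + vb / nb)
        else:
            raise ValueError("variant must be 'pooled' or 'welch'")
        t = (ma - mb) / denom
    t = np.where(mask & (denom > 0), t, np.nan)
    t = np.where(mask, t, np.nan)
    residuals = np.concatenate([a - ma, b - mb], axis=0)
    return t, residuals


def estimate_fwhm(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_mm,
) -> SmoothnessEstimate:
    """Estimate the effective Gaussian FWHM of residual fields per axis.

    Uses the first-spatial-difference variance ratio pooled over volumes:
    FWHM_d = voxel_d * sqrt(-2 ln 2 / ln(1 - v_d / (2 v))). Axes where
    v_d >= 2v (rougher than iid resolvable) are NaN.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim == 3:
        res = res[None]
    if res.shape[0] < 2:
        raise InsufficientDataError("need >= 2 residual volumes")
    mask = np.asarray(mask, dtype=bool)
    vox = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))

    ss_val = 0.0
    n_val = 0
    ss_diff = np.zeros(3)
    n_diff = np.zeros(3, dtype=int)
    for vol in res:
        vals = vol[mask]
        if vals.std() == 0:
            raise DegenerateInputError("constant residual volume")
        vals = vals - vals.mean()
        ss_val += float(np.sum(vals ** 2))
        n_val += vals.size
        for d in range(3):
            sl_hi = [slice(None)] * 3
            sl_lo = [slice(None)] * 3
            sl_hi[d] = slice(1, None)
            sl_lo[d] = slice(None, -1)
            pair = mask[tuple(sl_hi)] & mask[tuple(sl_lo)]
            diffs = (vol[tuple(sl_hi)] - vol[tuple(sl_lo)])[pair]
            ss_diff[d] += float(np.sum(diffs ** 2))
            n_diff[d] += diffs.size
    v = ss_val / max(n_val - 1, 1)
    fwhm = []
    for d in range(3):
        if n_diff[d] < 2:
            fwhm.append(float("nan"))
            continue
        vd = ss_diff[d] / n_diff[d]
        ratio = 1.0 - vd / (2.0 * v)
        if ratio <= 0:
            fwhm.append(float("nan"))  # rougher than resolvable
        else:
            fwhm.append(float(vox[d] * np.sqrt(-2.0 * np.log(2.0) / np.log(ratio))))
    return SmoothnessEstimate(fwhm_mm=tuple(fwhm))


def _max_cluster_size(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))))


def alphasim_min_cluster(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_p: float,
    voxel_mm,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    connectivity: int = 26,
    seed: int | None = None,
    two_sided: bool = True,
) -> AlphaSimResult:
    """Monte-Carlo minimum cluster extent controlling FWE at ``alpha``.

    Each iteration simulates an iid Gaussian field on the grid, smooths it
    to the requested FWHM, re-standardizes within the mask, thresholds at
    the voxel p, and records the largest suprathreshold cluster. The
    returned size is the smallest k whose empirical P(max >= k) <= alpha.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    if not np.isfinite(fwhm_mm) or fwhm_mm < 0:
        raise DegenerateInputError("unresolvable smoothness")
    vox = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    structure = connectivity_structure(connectivity)
    if two_sided:
        zthr = sps.norm.isf(voxel_p / 2.0)
    else:
        zthr = sps.norm.isf(voxel_p)
    rng = np.random.default_rng(seed)

    max_sizes = np.zeros(n_iterations, dtype=int)
    for i in range(n_iterations):
        field_ = rng.standard_normal(mask.shape)
        if fwhm_mm > 0:
            field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
        vals = field_[mask]
        field_ = (field_ - vals.mean()) / vals.std()
        supra = mask & (
            (np.abs(field_) > zthr) if two_sided else (field_ > zthr)
        )
        max_sizes[i] = _max_cluster_size(supra, structure)

    k = 1
    while np.mean(max_sizes >= k) > alpha:
        k += 1
    return AlphaSimResult(
        voxel_p=voxel_p,
        alpha=alpha,
        min_cluster_voxels=int(k),
        n_iterations=n_iterations,
        connectivity=connectivity,
        fwhm_mm=float(fwhm_mm),
        null_max_sizes=max_sizes,
    )


def extract_clusters(
    stat_map: np.ndarray,
    mask: np.ndarray,
    voxel_threshold: float,
    min_cluster_voxels: int = 1,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
    voxel_mm=None,
    two_sided: bool = True,
) -> ClusterTable:
    """Connected components of suprathreshold voxels, size-filtered.

    Threshold is on the statistic (|stat| > thr when two-sided). Peaks are
    the max-|stat| voxel per cluster; ties go to the smallest linear index.
    """
    stat = np.asarray(stat_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    if voxel_mm is None:
        voxel_mm = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    voxel_vol = float(np.prod(voxel_mm))
    finite = np.isfinite(stat)
    if two_sided:
        supra = mask & finite & (np.abs(stat) > voxel_threshold)
    else:
        supra = mask & finite & (stat > voxel_threshold)
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(supra, structure=structure)
    clusters = []
    out_labels = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n + 1):
        where = labels == lab
        size = int(where.sum())
        if size < min_cluster_voxels:
            continue
        next_label += 1
        out_labels[where] = next_label
        absvals = np.where(where, np.abs(stat), -np.inf)
        peak_flat = int(np.argmax(absvals))  # argmax takes first max: tie rule
        peak_voxel = np.unravel_index(peak_flat, stat.shape)
        peak_mm = (np.asarray(affine) @ np.array([*peak_voxel, 1.0]))[:3]
        clusters.append(
            Cluster(
                label=next_label,
                size_voxels=size,
                size_mm3=size * voxel_vol,
                peak_voxel=tuple(int(v) for v in peak_voxel),
                peak_mm=tuple(float(v) for v in peak_mm),
                peak_stat=float(stat[peak_voxel]),
            )
        )
    clusters.sort(key=lambda c: -c.size_voxels)
    return ClusterTable(clusters=clusters, labels=out_labels)
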