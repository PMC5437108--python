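"""Diffusion tensor fitting, FA/LDH maps, and deterministic FACT tracking.

Tensors are fit voxel-wise by log-linear least squares; streamlines follow
the per-voxel principal eigenvector from voxel boundary to voxel boundary
with angle and FA stopping rules; local diffusion homogeneity is Kendall's
coefficient of concordance of the raw weighted-signal series over a voxel
neighborhood.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .errors import DegenerateInputError, GridMismatchError, InsufficientDataError

__all__ = [
    "GradientTable",
    "TensorField",
    "Streamline",
    "TractMask",
    "IntegrityStats",
    "fit_tensor",
    "fa_from_evals",
    "fact_track",
    "tract_mask_between",
    "group_count_mask",
    "ldh_map",
    "tract_integrity",
]

# eigenvalue gap below which the principal direction is unreliable
_DEGENERATE_EVAL_GAP = 1e-8


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient directions and b-values (FSL bvec/bval style)."""

    bvecs: np.ndarray  # n x 3; zero rows for b0
    bvals: np.ndarray  # n

    def __post_init__(self):
        bvecs = np.asarray(self.bvecs, dtype=float)
        bvals = np.asarray(self.bvals, dtype=float)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3 or bvals.shape != (bvecs.shape[0],):
            raise ValueError("bvecs must be n x 3 with matching bvals")
        w = bvals > 0
        if w.sum() < 6:
            raise InsufficientDataError("need >= 6 weighted directions")
        norms = np.linalg.norm(bvecs[w], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted directions must be unit vectors")
        if not np.any(~w):
            raise InsufficientDataError("need >= 1 b0 volume")

    @property
    def weighted(self) -> np.ndarray:
        return self.bvals > 0


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors and their eigensystem."""

    tensors: np.ndarray   # (..., 3, 3) mm^2/s
    evals: np.ndarray     # (..., 3) descending
    evecs: np.ndarray     # (..., 3, 3) columns match evals
    fa: np.ndarray        # (...)
    valid: np.ndarray     # (...) bool: fit usable
    clamped: np.ndarray   # (...) bool: negative eigenvalues clamped

    @property
    def e1(self) -> np.ndarray:
        return self.evecs[..., :, 0]

    @property
    def direction_reliable(self) -> np.ndarray:
        return self.valid & (
            (self.evals[..., 0] - self.evals[..., 1]) > _DEGENERATE_EVAL_GAP
        )


@dataclass
class Streamline:
    points: np.ndarray          # m x 3 continuous voxel coordinates
    seed_voxel: tuple
    termination: tuple          # (backward reason, forward reason)
    visited: tuple              # voxel index tuples, in order


@dataclass
class TractMask:
    mask: np.ndarray
    roi_a_label: str = "A"
    roi_b_label: str = "B"
    n_streamlines: int = 0


@dataclass(frozen=True)
class IntegrityStats:
    mean_fa: float
    mean_ldh: float
    n_voxels: int


def _design(gtab: GradientTable) -> np.ndarray:
    g = gtab.bvecs[gtab.weighted]
    b = gtab.bvals[gtab.weighted]
    return b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||; 0 for null tensors."""
    ev = np.asarray(evals, dtype=float)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((ev - md) ** 2, axis=-1))
    den = np.sqrt(np.sum(ev ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def fit_tensor(
    dwi: np.ndarray, gtab: GradientTable, mask: np.ndarray | None = None
) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Solves ln(S_k / S0) = -b_k g_k^T D g_k. Voxels with non-positive signal
    anywhere are flagged invalid; negative eigenvalues are clamped to zero
    and flagged.
    """
    x = np.asarray(dwi, dtype=float)
    if x.ndim != 4 or x.shape[-1] != gtab.bvals.size:
        raise ValueError("dwi must be 4D with one volume per gradient entry")
    shape = x.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    s0 = x[..., ~gtab.weighted].mean(axis=-1)
    sw = x[..., gtab.weighted]
    valid = mask & (s0 > 0) & np.all(sw > 0, axis=-1)

    design = _design(gtab)
    pinv = np.linalg.pinv(design)

    flat = sw[valid]
    logs = -np.log(flat / s0[valid][:, None])
    d6 = logs @ pinv.T  # V x 6: dxx dyy dzz dxy dxz dyz

    tensors = np.zeros((*shape, 3, 3))
    t = np.zeros((d6.shape[0], 3, 3))
    t[:, 0, 0] = d6[:, 0]
    t[:, 1, 1] = d6[:, 1]
    t[:, 2, 2] = d6[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = d6[:, 3]
    t[:, 0, 2] = t[:, 2, 0] = d6[:, 4]
    t[:, 1, 2] = t[:, 2, 1] = d6[:, 5]
    tensors[valid] = t

    evals = np.zeros((*shape, 3))
    evecs = np.zeros((*shape, 3, 3))
    w, v = np.linalg.eigh(t)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    clamped_flat = np.any(w < 0, axis=-1)
    w = np.clip(w, 0.0, None)
    evals[valid] = w
    evecs[valid] = v
    clamped = np.zeros(shape, dtype=bool)
    clamped[valid] = clamped_flat

    fa = np.zeros(shape)
    fa[valid] = fa_from_evals(w)
    return TensorField(
        tensors=tensors, evals=evals, evecs=evecs, fa=fa,
        valid=valid, clamped=clamped,
    )


def _track_one_direction(
    start: np.ndarray,
    d0: np.ndarray,
    e1: np.ndarray,
    fa: np.ndarray,
    reliable: np.ndarray,
    fa_min: float,
    cos_max: float,
    max_steps: int,
):
    """Propagate from ``start`` along d0, voxel boundary to voxel boundary."""
    shape = fa.shape
    points = [start.copy()]
    visited = []
    p = start.copy()
    d = d0 / np.linalg.norm(d0)
    voxel = tuple(int(np.floor(c)) for c in p)
    visited.append(voxel)
    reason = "exit"
    for _ in range(max_steps):
        # distance to the exit face of the current voxel along d
        t_exit = np.inf
        for ax in range(3):
            if d[ax] > 1e-12:
                t_ax = (voxel[ax] + 1 - p[ax]) / d[ax]
            elif d[ax] < -1e-12:
                t_ax = (voxel[ax] - p[ax]) / d[ax]
            else:
                continue
            t_exit = min(t_exit, t_ax)
        if not np.isfinite(t_exit):
            reason = "angle"  # degenerate direction
            break
        p = p + (t_exit + 1e-6) * d
        points.append(p.copy())
        nxt = tuple(int(np.floor(c)) for c in p)
        if any(c < 0 or c >= shape[ax] for ax, c in enumerate(nxt)):
            reason = "exit"
            break
        if fa[nxt] < fa_min:
            visited.append(nxt)
            reason = "fa"
            break
        if not reliable[nxt]:
            visited.append(nxt)
            reason = "fa"
            break
        nd = e1[nxt].astype(float)
        if nd @ d < 0:  # antipodal sign disambiguation
            nd = -nd
        nd = nd / np.linalg.norm(nd)
        if nd @ d < cos_max:
            visited.append(nxt)
            reason = "angle"
            break
        visited.append(nxt)
        voxel = nxt
        d = nd
    return points, visited, reason


def fact_track(
    tensor_field: TensorField,
    seed_voxels: Sequence[tuple],
    seeds_per_voxel: int = 100,
    angle_max_deg: float = 45.0,
    fa_min: float = 0.15,
    rng_seed: int | None = None,
    max_steps: int | None = None,
) -> list:
    """Deterministic FACT streamlines from random in-voxel start points.

    Each start point is propagated bidirectionally along the per-voxel
    constant principal direction, stepping to the voxel boundary, entering
    the next voxel, and re-orienting with the sign that minimizes turning.
    Stops on FA < fa_min, turning angle > angle_max_deg, or grid exit.
    Seeds in voxels below the FA floor or with an unreliable direction are
    skipped.
    """
    if len(seed_voxels) == 0:
        raise InsufficientDataError("empty seed set")
    fa = tensor_field.fa
    e1 = tensor_field.e1
    reliable = tensor_field.direction_reliable
    shape = fa.shape
    cos_max = float(np.cos(np.deg2rad(angle_max_deg)))
    if max_steps is None:
        max_steps = 10 * int(max(shape))
    rng = np.random.default_rng(rng_seed)

    streamlines = []
    for voxel in seed_voxels:
        voxel = tuple(int(v) for v in voxel)
        if fa[voxel] < fa_min or not reliable[voxel]:
            continue
        d0 = e1[voxel].astype(float)
        offsets = rng.random((seeds_per_voxel, 3))
        for off in offsets:
            start = np.asarray(voxel, dtype=float) + off
            fw_pts, fw_vis, fw_reason = _track_one_direction(
                start, d0, e1, fa, reliable, fa_min, cos_max, max_steps
            )
            bw_pts, bw_vis, bw_reason = _track_one_direction(
                start, -d0, e1, fa, reliable, fa_min, cos_max, max_steps
            )
            points = np.asarray(bw_pts[::-1] + fw_pts[1:])
            visited = tuple(dict.fromkeys(bw_vis[::-1] + fw_vis))
            streamlines.append(
                Streamline(
                    points=points,
                    seed_voxel=voxel,
                    termination=(bw_reason, fw_reason),
                    visited=visited,
                )
            )
    return streamlines


def tract_mask_between(
    streamlines: Sequence[Streamline],
    roi_a: np.ndarray,
    roi_b: np.ndarray,
    shape=None,
) -> TractMask:
    """Union of voxels traversed by streamlines that reach roi_b.

    Streamlines are assumed seeded in roi_a; a streamline qualifies if any
    visited voxel lies in roi_b. An empty mask is a valid outcome.
    """
    roi_b = np.asarray(roi_b, dtype=bool)
    if shape is None:
        shape = roi_b.shape
    mask = np.zeros(shape, dtype=bool)
    kept = 0
    for sl in streamlines:
        if any(roi_b[v] for v in sl.visited):
            kept += 1
            for v in sl.visited:
                mask[v] = True
    return TractMask(mask=mask, n_streamlines=kept)


def group_count_mask(
    subject_masks: Sequence[TractMask], min_subjects: int = 4
) -> TractMask:
    """Voxels present in at least ``min_subjects`` subject tract masks
    (default 4, i.e. a strict count > 3)."""
    if len(subject_masks) == 0:
        raise InsufficientDataError("need >= 1 subject mask")
    arrays = [np.asarray(m.mask, dtype=bool) for m in subject_masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise GridMismatchError("subject masks must share one grid")
    counts = np.sum(arrays, axis=0)
    return TractMask(mask=counts >= min_subjects)


def ldh_map(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray,
    include_b0: bool = False,
) -> np.ndarray:
    """Local diffusion homogeneity: Kendall's W of the weighted-signal
    series over each voxel's 27-neighborhood (in-mask members only).

    W = 12 * sum_i (R_i - m(k+1)/2)^2 / (m^2 (k^3 - k)) with m in-mask
    neighbors (voxel included) and k volumes; R_i is the rank sum for
    volume i across the m series. Voxels with fewer than 2 in-mask
    neighborhood members are NaN.
    """
    x = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    use = gtab.weighted | (np.full(gtab.bvals.shape, include_b0))
    series = x[..., use]
    k = int(series.shape[-1])
    if k < 2:
        raise InsufficientDataError("need >= 2 volumes for concordance")

    ranks = sps.rankdata(series, axis=-1)
    ranks = np.where(mask[..., None], ranks, 0.0)
    kernel = np.ones((3, 3, 3))
    m_count = ndimage.convolve(
        mask.astype(float), kernel, mode="constant", cval=0.0
    )
    rank_sums = np.empty_like(ranks)
    for i in range(k):
        rank_sums[..., i] = ndimage.convolve(
            ranks[..., i], kernel, mode="constant", cval=0.0
        )
    rbar = m_count[..., None] * (k + 1) / 2.0
    s = np.sum((rank_sums - rbar) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = 12.0 * s / (m_count ** 2 * (k ** 3 - k))
    w = np.where(mask & (m_count >= 2), w, np.nan)
    return w


def tract_integrity(
    tract: TractMask, fa_map: np.ndarray, ldh: np.ndarray
) -> IntegrityStats:
    """Arithmetic mean FA and LDH over the tract voxels."""
    m = np.asarray(tract.mask, dtype=bool)
    if not m.any():
        raise DegenerateInputError("empty tract mask")
    fa_vals = np.asarray(fa_map, dtype=float)[m]
    ldh_vals = np.asarray(ldh, dtype=float)[m]
    return IntegrityStats(
        mean_fa=float(np.nanmean(fa_vals)),
        mean_ldh=float(np.nanmean(ldh_vals)),
        n_voxels=int(m.sum()),
    )
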