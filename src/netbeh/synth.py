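"""Synthetic two-group cohort with planted, recoverable ground truth.

Generates, on one shared grid: gray-matter volume maps with a focal atrophy
region whose depth scales with a latent severity, BOLD-like series in which
a hub region's coupling to two target regions degrades with severity,
behavior scores linearly tied to severity (semantic tasks only), and
diffusion-weighted series with an anisotropic tract between the hub and the
first target whose principal diffusivity degrades with severity.

Controls have severity 0. Everything is deterministic given the seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import NetbehError
from .fmri import gaussian_smooth

__all__ = [
    "RoiSphere",
    "RoiBox",
    "SyntheticConfig",
    "Observation",
    "Cohort",
    "GroundTruth",
    "generate_cohort",
    "ground_truth",
    "make_gradient_scheme",
    "SEMANTIC_TASKS",
    "NONSEMANTIC_TASKS",
]

SEMANTIC_TASKS = (
    "oral_picture_naming",
    "picture_associative_matching",
    "word_associate_matching",
)
NONSEMANTIC_TASKS = ("calculation", "rey_o_recall")

# task -> (control mean, severity slope, noise sd)
_DEFAULT_TASKS = {
    "oral_picture_naming": (125.0, 85.0, 6.0),
    "picture_associative_matching": (66.7, 15.0, 2.0),
    "word_associate_matching": (67.0, 16.0, 2.0),
    "calculation": (6.4, 0.0, 0.8),
    "rey_o_recall": (17.0, 0.0, 6.0),
}


@dataclass(frozen=True)
class RoiSphere:
    center: tuple  # voxel coordinates (continuous allowed)
    radius: float  # voxels

    def mask(self, shape) -> np.ndarray:
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        d = np.linalg.norm(idx - np.asarray(self.center, dtype=float), axis=1)
        return (d <= self.radius).reshape(shape)


@dataclass(frozen=True)
class RoiBox:
    lo: tuple  # inclusive voxel corner
    hi: tuple  # inclusive voxel corner

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sl = tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))
        m[sl] = True
        return m


@dataclass(frozen=True)
class TubeSpec:
    """Voxels within ``radius`` voxels of the segment start->end."""

    start: tuple
    end: tuple
    radius: float

    def mask(self, shape) -> np.ndarray:
        a = np.asarray(self.start, dtype=float)
        b = np.asarray(self.end, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        idx = np.indices(shape).reshape(3, -1).T.astype(float) + 0.5
        t = np.clip((idx - a) @ ab / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        d = np.linalg.norm(idx - closest, axis=1)
        return (d <= self.radius).reshape(shape)

    @property
    def tangent(self) -> np.ndarray:
        v = np.asarray(self.end, dtype=float) - np.asarray(self.start, dtype=float)
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class NoiseSds:
    gmv: float = 0.08
    bold: float = 1.0
    behavior_scale: float = 1.0  # multiplies per-task noise sds
    dwi: float = 0.02  # additive Gaussian on a unit-S0 signal


@dataclass(frozen=True)
class SyntheticConfig:
    grid_shape: tuple = (20, 20, 14)
    voxel_mm: float = 3.0
    n_patients: int = 17
    n_observations: int = 21
    n_controls: int = 18
    tr_s: float = 2.0
    n_volumes: int = 200
    dwi_directions: int = 40
    b_value: float = 1000.0
    atrophy_roi: RoiBox = RoiBox(lo=(4, 5, 4), hi=(15, 14, 9))
    hub_roi: RoiSphere = RoiSphere(center=(6.0, 9.0, 6.0), radius=2.0)
    target_roi_1: RoiSphere = RoiSphere(center=(13.0, 9.0, 6.0), radius=2.0)
    target_roi_2: RoiSphere = RoiSphere(center=(9.0, 12.5, 6.0), radius=1.6)
    tract_path: TubeSpec = TubeSpec(
        start=(6.0, 9.0, 6.0), end=(13.0, 9.0, 6.0), radius=1.0
    )
    severity_range: tuple = (0.15, 0.95)
    severity_repeat_drift: float = 0.04
    beta_fc: float = 1.1       # hub latent-coupling loss per unit severity
    beta_gmv: float = 0.25     # atrophy depth per unit severity
    beta_behavior: float = 1.0 # multiplies per-task severity slopes
    beta_tract: float = 0.4    # principal diffusivity loss per unit severity
    latent_band_hz: tuple = (0.01, 0.08)
    hub_coupling: float = 0.85     # baseline latent loading of hub voxels
    target_coupling: float = 0.85  # latent loading of target voxels
    noise_sds: NoiseSds = NoiseSds()
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_volumes <= 10:
            raise NetbehError("n_volumes must exceed the discard count (10)")
        shape = self.grid_shape
        for name in ("atrophy_roi", "hub_roi", "target_roi_1", "target_roi_2"):
            m = getattr(self, name).mask(shape)
            if not m.any():
                raise NetbehError(f"{name} is empty")
        hub = self.hub_roi.mask(shape)
        t1 = self.target_roi_1.mask(shape)
        t2 = self.target_roi_2.mask(shape)
        if (hub & t1).any() or (hub & t2).any() or (t1 & t2).any():
            raise NetbehError("hub and target ROIs must be disjoint")
        atro = self.atrophy_roi.mask(shape)
        if not ((hub | t1 | t2) <= atro).all():
            raise NetbehError("hub/target ROIs must lie inside the atrophy ROI")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Observation:
    obs_id: str
    subject_id: str
    group: str          # "patient" | "control"
    obs_index: int      # 1-based observation number for the subject
    severity: float
    gmv: np.ndarray
    bold: np.ndarray    # (x, y, z, t) float32
    dwi: np.ndarray     # (x, y, z, n_grad) float32
    motion_summary: np.ndarray    # max |tx ty tz| mm, max |rx ry rz| deg
    motion_series: np.ndarray     # t x 6
    confounds: np.ndarray         # t x 8 (6 motion + wm + csf proxies)
    behavior: dict                # task -> raw score


@dataclass
class Cohort:
    config: SyntheticConfig
    affine: np.ndarray
    brain_mask: np.ndarray
    observations: list
    bvecs: np.ndarray
    bvals: np.ndarray

    @property
    def patients(self) -> list:
        return [o for o in self.observations if o.group == "patient"]

    @property
    def controls(self) -> list:
        return [o for o in self.observations if o.group == "control"]

    def behavior_table(self):
        import pandas as pd

        rows = []
        for o in self.observations:
            for task, score in o.behavior.items():
                rows.append(
                    {
                        "observation_id": o.obs_id,
                        "patient_id": o.subject_id,
                        "group": o.group,
                        "obs_index": o.obs_index,
                        "task_id": task,
                        "raw_score": score,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    atrophy_mask: np.ndarray
    hub_mask: np.ndarray
    target_mask_1: np.ndarray
    target_mask_2: np.ndarray
    tract_mask: np.ndarray
    brain_mask: np.ndarray
    severities: dict          # obs_id -> severity
    expected_signs: dict      # association name -> +1 / -1 / 0


def make_affine(config: SyntheticConfig) -> np.ndarray:
    aff = np.diag([config.voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -np.asarray(config.grid_shape) * config.voxel_mm / 2.0
    return aff


def make_gradient_scheme(
    n_directions: int, b_value: float
) -> tuple[np.ndarray, np.ndarray]:
    """One b0 followed by quasi-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n_directions, dtype=float)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_directions
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z ** 2, 0, 1))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    bvals = np.concatenate([[0.0], np.full(n_directions, b_value)])
    return bvecs, bvals


def _brain_mask(shape) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.48
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    q = np.sum(((idx - center) / semi) ** 2, axis=1)
    return (q <= 1.0).reshape(shape)


def _band_limited_series(rng, n, tr_s, band) -> np.ndarray:
    """Unit-variance series with spectral support limited to ``band``."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    spec = np.zeros(freqs.size, dtype=complex)
    phases = rng.uniform(0, 2 * np.pi, int(keep.sum()))
    amps = rng.normal(1.0, 0.2, int(keep.sum()))
    spec[keep] = amps * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / x.std()


def _observation_roster(config: SyntheticConfig) -> list:
    """(subject_id, group, obs_index) rows: repeats first, then singletons,
    then controls. Repeat structure: one triple + two doubles by default."""
    n_extra = config.n_observations - config.n_patients
    rows = []
    repeats = []
    if n_extra > 0:
        # subject 1 gets min(n_extra, 2) extra visits, then one extra each
        left = n_extra
        sid = 1
        while left > 0:
            take = 2 if (sid == 1 and left >= 2) else 1
            repeats.append((sid, 1 + take))
            left -= take
            sid += 1
    n_visits = {i: 1 for i in range(1, config.n_patients + 1)}
    for sid, total in repeats:
        n_visits[sid] = total
    for sid in range(1, config.n_patients + 1):
        for k in range(1, n_visits[sid] + 1):
            rows.append((f"P{sid:02d}", "patient", k))
    for cid in range(1, config.n_controls + 1):
        rows.append((f"C{cid:02d}", "control", 1))
    return rows


def _planted_tensor(tangent: np.ndarray, lam1: float, lam23: float) -> np.ndarray:
    t = tangent / np.linalg.norm(tangent)
    # complete an orthonormal frame around the tangent
    helper = np.array([0.0, 0.0, 1.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return lam1 * np.outer(t, t) + lam23 * (np.outer(u, u) + np.outer(v, v))


ISO_DIFFUSIVITY = 0.7e-3       # mm^2/s, non-tract voxels
TRACT_LAMBDA1 = 1.7e-3
TRACT_LAMBDA23 = 0.3e-3


def _dwi_signal(
    config: SyntheticConfig,
    truth: "GroundTruth",
    severity: float,
    bvecs: np.ndarray,
    bvals: np.ndarray,
    rng,
) -> np.ndarray:
    shape = config.grid_shape
    n = bvals.size
    quad = np.empty((n,))
    sig = np.empty((*shape, n), dtype=np.float32)
    iso = np.exp(-bvals * ISO_DIFFUSIVITY)
    sig[...] = iso.astype(np.float32)
    lam1 = TRACT_LAMBDA1 * (1.0 - config.beta_tract * severity)
    d_tract = _planted_tensor(config.tract_path.tangent, lam1, TRACT_LAMBDA23)
    for k in range(n):
        g = bvecs[k]
        quad[k] = g @ d_tract @ g
    tract_signal = np.exp(-bvals * quad)
    sig[truth.tract_mask] = tract_signal.astype(np.float32)
    sig[~truth.brain_mask] = 0.05
    if config.noise_sds.dwi > 0:
        sig = sig + rng.normal(
            0.0, config.noise_sds.dwi, sig.shape
        ).astype(np.float32)
        np.clip(sig, 1e-4, None, out=sig)
    return sig


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Planted masks, per-observation severities, and association signs."""
    shape = config.grid_shape
    brain = _brain_mask(shape)
    rng = np.random.default_rng(config.rng_seed)
    roster = _observation_roster(config)
    lo, hi = config.severity_range
    base = {}
    severities = {}
    for sid, group, k in roster:
        obs_id = f"{sid}-{k}"
        if group == "control":
            severities[obs_id] = 0.0
            continue
        if sid not in base:
            base[sid] = float(rng.uniform(lo, hi))
        severities[obs_id] = float(
            min(1.0, base[sid] + config.severity_repeat_drift * (k - 1))
        )
    sign = lambda b: int(np.sign(b))
    expected_signs = {
        # worse severity -> lower score and lower degree/FC/FA: positive
        # behavior association when both couplings are positive
        "degree_vs_composite": sign(config.beta_fc * config.beta_behavior),
        "seed_fc_vs_composite": sign(config.beta_fc * config.beta_behavior),
        "fa_vs_composite": sign(config.beta_tract * config.beta_behavior),
        "patient_minus_control_gmv": -sign(config.beta_gmv),
        "patient_minus_control_degree": -sign(config.beta_fc),
        "patient_minus_control_fa": -sign(config.beta_tract),
    }
    return GroundTruth(
        atrophy_mask=config.atrophy_roi.mask(shape) & brain,
        hub_mask=config.hub_roi.mask(shape),
        target_mask_1=config.target_roi_1.mask(shape),
        target_mask_2=config.target_roi_2.mask(shape),
        tract_mask=config.tract_path.mask(shape),
        brain_mask=brain,
        severities=severities,
        expected_signs=expected_signs,
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Build the full synthetic cohort; byte-identical for equal seeds."""
    shape = config.grid_shape
    affine = make_affine(config)
    truth = ground_truth(config)
    brain = truth.brain_mask
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 0xC0401])
    )
    bvecs, bvals = make_gradient_scheme(config.dwi_directions, config.b_value)

    # fixed anatomical baseline shared by everyone
    baseline_rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 0xBA5E])
    )
    baseline = 0.6 + gaussian_smooth(
        baseline_rng.normal(0, 0.15, shape), 9.0, [config.voxel_mm] * 3
    )

    hub = truth.hub_mask
    targets = truth.target_mask_1 | truth.target_mask_2
    t = config.n_volumes
    noise = config.noise_sds

    observations = []
    for sid, group, k in _observation_roster(config):
        obs_id = f"{sid}-{k}"
        s = truth.severities[obs_id]

        gmv = baseline.copy()
        gmv[truth.atrophy_mask] -= config.beta_gmv * s
        gmv += gaussian_smooth(
            rng.normal(0, noise.gmv, shape), 6.0, [config.voxel_mm] * 3
        )
        gmv[~brain] = 0.0

        latent = _band_limited_series(rng, t, config.tr_s, config.latent_band_hz)
        alpha_hub = config.hub_coupling * max(0.0, 1.0 - config.beta_fc * s)
        bold = rng.normal(0, noise.bold, (*shape, t)).astype(np.float32)
        # hub/target series are built on an orthonormal basis so that the
        # raw pairwise correlation is exactly alpha_v * alpha_w: idiosyncratic
        # components are orthogonalized against the latent, the constant
        # vector, and each other
        n_hub = int(hub.sum())
        n_tgt = int(targets.sum())
        raw = rng.standard_normal((t, n_hub + n_tgt))
        lhat = latent / np.linalg.norm(latent)
        if t >= n_hub + n_tgt + 2:
            # full orthonormal basis: correlations are exact
            basis = np.column_stack([np.ones(t), latent, raw])
            q, _ = np.linalg.qr(basis)
            eps = q[:, 2:]
        else:
            # too few frames for mutual orthogonality: only remove the
            # constant and latent components (correlations approximate)
            ones = np.ones(t) / np.sqrt(t)
            eps = raw - np.outer(ones, ones @ raw) - np.outer(lhat, lhat @ raw)
            eps /= np.linalg.norm(eps, axis=0)
        scale = np.sqrt(t)  # restore ~unit-variance amplitude
        hub_sig = (
            alpha_hub * lhat[:, None]
            + np.sqrt(max(0.0, 1 - alpha_hub ** 2)) * eps[:, :n_hub]
        ) * scale
        tgt_sig = (
            config.target_coupling * lhat[:, None]
            + np.sqrt(1 - config.target_coupling ** 2) * eps[:, n_hub:]
        ) * scale
        bold[hub] = hub_sig.T.astype(np.float32)
        bold[targets] = tgt_sig.T.astype(np.float32)
        bold[~brain] = 0.0
        bold += 100.0  # scanner-like positive baseline

        motion_series = np.cumsum(
            rng.normal(0, 0.01, (t, 6)), axis=0
        )
        motion_summary = np.abs(motion_series).max(axis=0)
        wm = _band_limited_series(rng, t, config.tr_s, (0.0, 0.12))
        csf = _band_limited_series(rng, t, config.tr_s, (0.0, 0.12))
        confounds = np.column_stack([motion_series, wm, csf])

        dwi = _dwi_signal(config, truth, s, bvecs, bvals, rng)

        behavior = {}
        for task, (mean, slope, sd) in _DEFAULT_TASKS.items():
            coupled = task in SEMANTIC_TASKS
            eff = config.beta_behavior * slope * s if coupled else 0.0
            behavior[task] = float(
                mean - eff + rng.normal(0, sd * noise.behavior_scale)
            )

        observations.append(
            Observation(
                obs_id=obs_id,
                subject_id=sid,
                group=group,
                obs_index=k,
                severity=s,
                gmv=gmv,
                bold=bold,
                dwi=dwi,
                motion_summary=motion_summary,
                motion_series=motion_series,
                confounds=confounds,
                behavior=behavior,
            )
        )

    return Cohort(
        config=config,
        affine=affine,
        brain_mask=brain,
        observations=observations,
        bvecs=bvecs,
        bvals=bvals,
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Serialize the cohort: NIfTI volumes, bvec/bval, behavior TSV,
    ground-truth JSON."""
    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    aff = cohort.affine
    for o in cohort.observations:
        sub = out / o.obs_id
        sub.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(o.gmv.astype(np.float32), aff), sub / "gmv.nii.gz")
        nib.save(nib.Nifti1Image(o.bold.astype(np.float32), aff), sub / "bold.nii.gz")
        nib.save(nib.Nifti1Image(o.dwi.astype(np.float32), aff), sub / "dwi.nii.gz")
        np.savetxt(sub / "motion.tsv", o.motion_series, delimiter="\t")
        np.savetxt(sub / "confounds.tsv", o.confounds, delimiter="\t")
    np.savetxt(out / "dwi.bvec", cohort.bvecs.T, fmt="%.8f")
    np.savetxt(out / "dwi.bval", cohort.bvals[None], fmt="%.1f")
    cohort.behavior_table().to_csv(out / "behavior.tsv", sep="\t", index=False)
    truth = ground_truth(cohort.config)
    nib.save(
        nib.Nifti1Image(truth.brain_mask.astype(np.uint8), aff),
        out / "brain_mask.nii.gz",
    )
    payload = {
        "severities": truth.severities,
        "expected_signs": truth.expected_signs,
        "masks": {
            name: [list(map(int, v)) for v in np.argwhere(getattr(truth, name))]
            for name in (
                "atrophy_mask", "hub_mask", "target_mask_1",
                "target_mask_2", "tract_mask",
            )
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
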