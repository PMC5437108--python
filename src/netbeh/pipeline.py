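"""End-to-end driver: behavior standardization, atrophy network, degree
centrality contrast, seed extraction, seed-FC behavior mapping with
confound-controlled validation and specificity testing, and tract-integrity
analysis, on a synthetic or user-supplied cohort.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as ci
from . import dwi as dw
from . import fmri as fm
from . import stats as st
from . import synth
from .errors import DegenerateInputError, StageError
from .io import save_json, save_volume

log = logging.getLogger("netbeh")

__all__ = [
    "PipelineConfig",
    "ResultsBundle",
    "run_pipeline",
    "validate_with_covariates",
    "specificity_test",
    "save_results",
    "write_report",
]

COVARIATE_LABELS = (
    "total_gmv",
    "seed_gmv",
    "seed_mfalff",
    "observation_index",
)


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: synth.SyntheticConfig = synth.SyntheticConfig()
    discard_volumes: int = 10
    motion_trans_limit_mm: float = 2.5
    motion_rot_limit_deg: float = 2.5
    smooth_fwhm_gmv_mm: float = 8.0
    smooth_fwhm_bold_mm: float = 4.0
    band_hz: tuple = (0.01, 0.10)
    r_threshold: float = 0.10
    seed_radius_mm: float = 3.0
    atrophy_voxel_p: float = 0.05
    atrophy_alpha: float = 0.05
    degree_voxel_p: float = 0.05
    degree_alpha: float = 0.05
    fc_voxel_p: float = 0.05
    fc_alpha: float = 0.001
    alphasim_iterations: int = 1000
    connectivity: int = 26
    group_t_variant: str = "pooled"
    run_structural: bool = True
    seeds_per_voxel: int = 100
    angle_max_deg: float = 45.0
    fa_min: float = 0.15
    tract_min_subjects: int = 4
    rng_seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return self.replace(
            rng_seed=seed, synthetic=self.synthetic.replace(rng_seed=seed)
        )


@dataclass
class CorrelationRow:
    name: str
    result: st.CorrelationResult

    def to_dict(self) -> dict:
        r = self.result
        return {
            "name": self.name,
            "r": r.r,
            "df": r.df,
            "p": r.p,
            "n": r.n,
            "covariates": list(r.covariate_labels),
        }


@dataclass
class ResultsBundle:
    config: PipelineConfig
    behavior: dict
    atrophy: dict
    degree: dict
    seed_fc: dict
    validation: dict
    tract: dict
    maps: dict = field(default_factory=dict)  # name -> (array, affine)

    def any_significant_behavior_association(self, alpha: float = 0.05) -> bool:
        """True if any stage reported a behavior association at its stated
        threshold: a cluster-corrected degree region whose seed degree
        correlates with the composite, any surviving FC-behavior cluster, or
        a tract-integrity correlation on a surviving tract."""
        deg = (
            self.degree.get("cluster_significant", False)
            and self.degree.get("behavior_correlation", {}).get("p", 1.0) < alpha
        )
        fc = self.seed_fc.get("n_clusters", 0) > 0
        tract = any(
            row.get("semantic", {}).get("p", 1.0) < alpha
            for row in self.tract.get("integrity_correlations", [])
        )
        return bool(deg or fc or tract)

    def to_dict(self) -> dict:
        return {
            "settings": _settings_dict(self.config),
            "behavior": self.behavior,
            "atrophy": self.atrophy,
            "degree": self.degree,
            "seed_fc": self.seed_fc,
            "validation": self.validation,
            "tract": self.tract,
        }


def _settings_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _corr_dict(res: st.CorrelationResult) -> dict:
    return {
        "r": res.r,
        "df": res.df,
        "p": res.p,
        "n": res.n,
        "covariates": list(res.covariate_labels),
    }


# ---------------------------------------------------------------------------
# stage: behavior
# ---------------------------------------------------------------------------

def _behavior_stage(cohort: synth.Cohort) -> dict:
    patients = cohort.patients
    controls = cohort.controls
    tasks = list(synth.SEMANTIC_TASKS + synth.NONSEMANTIC_TASKS)

    control_samples = {
        task: st.ControlSample.from_values([o.behavior[task] for o in controls])
        for task in tasks
    }
    corrected: dict[str, dict[str, st.CorrectedScore]] = {}
    for o in patients:
        corrected[o.obs_id] = {
            task: st.crawford_howell_t(
                o.behavior[task], control_samples[task], task_id=task
            )
            for task in tasks
        }
    sem_matrix = np.array(
        [
            [corrected[o.obs_id][t].t_value for t in synth.SEMANTIC_TASKS]
            for o in patients
        ]
    )
    composites = st.composite_semantic(
        sem_matrix, [o.obs_id for o in patients]
    )
    composite_by_obs = {c.observation_id: c.value for c in composites}

    group_tests = {}
    for task in tasks:
        ps = np.array([o.behavior[task] for o in patients])
        cs = np.array([o.behavior[task] for o in controls])
        wt, wdf = st.welch_t(
            ps.mean(), ps.std(ddof=1), ps.size, cs.mean(), cs.std(ddof=1), cs.size
        )
        pt, pdf = st.student_t_pooled(
            ps.mean(), ps.std(ddof=1), ps.size, cs.mean(), cs.std(ddof=1), cs.size
        )
        group_tests[task] = {
            "welch_t": wt, "welch_df": wdf, "pooled_t": pt, "pooled_df": pdf,
            "patient_mean": float(ps.mean()), "patient_sd": float(ps.std(ddof=1)),
            "control_mean": float(cs.mean()), "control_sd": float(cs.std(ddof=1)),
        }

    return {
        "corrected": corrected,
        "composite_by_obs": composite_by_obs,
        "group_tests": group_tests,
        "n_patient_observations": len(patients),
        "n_controls": len(controls),
    }


# ---------------------------------------------------------------------------
# stage: atrophy network
# ---------------------------------------------------------------------------

def _atrophy_stage(cohort: synth.Cohort, config: PipelineConfig) -> dict:
    vox = [config.synthetic.voxel_mm] * 3
    brain = cohort.brain_mask
    smoothed = {
        o.obs_id: fm.gaussian_smooth(o.gmv, config.smooth_fwhm_gmv_mm, vox)
        for o in cohort.observations
    }
    pat = np.stack([smoothed[o.obs_id] for o in cohort.patients])
    con = np.stack([smoothed[o.obs_id] for o in cohort.controls])
    tmap, residuals = ci.group_t_map(
        pat, con, brain, variant=config.group_t_variant
    )
    fwhm = ci.estimate_fwhm(residuals, brain, vox)
    sim = ci.alphasim_min_cluster(
        brain,
        fwhm.mean_fwhm_mm,
        config.atrophy_voxel_p,
        vox,
        alpha=config.atrophy_alpha,
        n_iterations=config.alphasim_iterations,
        connectivity=config.connectivity,
        seed=config.rng_seed + 101,
    )
    from scipy import stats as sps

    df = len(cohort.patients) + len(cohort.controls) - 2
    tthr = float(sps.t.isf(config.atrophy_voxel_p / 2.0, df))
    table = ci.extract_clusters(
        tmap, brain, tthr, sim.min_cluster_voxels,
        connectivity=config.connectivity, affine=cohort.affine,
    )
    # atrophy = regions where patients are LOWER (negative peaks)
    neg = [c for c in table if c.peak_stat < 0]
    mask = np.isin(table.labels, [c.label for c in neg]) & (table.labels > 0)
    if not mask.any():
        raise StageError(
            "atrophy", "no surviving atrophy cluster; cannot define the "
            "analysis mask (empty atrophy network)"
        )
    log.info("atrophy: %d clusters, mask %d voxels", len(neg), int(mask.sum()))
    return {
        "t_map": tmap,
        "smoothed_gmv": smoothed,
        "fwhm_mm": fwhm.fwhm_mm,
        "alphasim": sim.to_dict(),
        "voxel_t_threshold": tthr,
        "clusters": [dataclasses.asdict(c) for c in table],
        "mask": mask,
    }


# ---------------------------------------------------------------------------
# stage: BOLD preprocessing (per observation)
# ---------------------------------------------------------------------------

def _preprocess_bold(cohort: synth.Cohort, config: PipelineConfig, mask) -> dict:
    from scipy.signal import detrend as sp_detrend

    vox = [config.synthetic.voxel_mm] * 3
    out = {}
    for o in cohort.observations:
        keep = fm.motion_exclude(
            o.motion_summary,
            config.motion_trans_limit_mm,
            config.motion_rot_limit_deg,
        )
        if not keep:
            log.info("motion exclusion: dropping %s", o.obs_id)
            out[o.obs_id] = None
            continue
        bold = fm.BoldSeries(
            data=o.bold.astype(np.float64), tr_s=cohort.config.tr_s,
            affine=cohort.affine,
        )
        bold = fm.discard_initial_volumes(bold, config.discard_volumes)
        confounds = o.confounds[config.discard_volumes:]
        bold = fm.BoldSeries(
            data=fm.gaussian_smooth(bold.data, config.smooth_fwhm_bold_mm, vox),
            tr_s=bold.tr_s, affine=bold.affine,
        )
        detrended = sp_detrend(bold.data, axis=-1, type="linear")
        mfalff = fm.mfalff_map(
            fm.BoldSeries(detrended, bold.tr_s, bold.affine),
            cohort.brain_mask, config.band_hz,
        )
        bold = fm.detrend_bandpass(bold, *config.band_hz)
        bold = fm.nuisance_regress(bold, confounds)
        out[o.obs_id] = {
            "series": bold.data[mask].astype(np.float32),  # V x t, mask order
            "mfalff": mfalff,
            "n_frames": bold.n_volumes,
        }
    return out


def _series_to_bold(entry, mask, tr_s, affine) -> fm.BoldSeries:
    data = np.zeros((*mask.shape, entry["series"].shape[-1]))
    data[mask] = entry["series"]
    return fm.BoldSeries(data=data, tr_s=tr_s, affine=affine)


# ---------------------------------------------------------------------------
# stage: degree centrality
# ---------------------------------------------------------------------------

def _degree_stage(
    cohort: synth.Cohort,
    config: PipelineConfig,
    mask: np.ndarray,
    prep: dict,
    composites: dict,
) -> dict:
    vox = [config.synthetic.voxel_mm] * 3
    zmaps = {}
    for o in cohort.observations:
        entry = prep[o.obs_id]
        if entry is None:
            continue
        bold = _series_to_bold(entry, mask, cohort.config.tr_s, cohort.affine)
        fc, valid = fm.fc_matrix(bold, mask)
        deg = fm.degree_map(fc, config.r_threshold)
        vol = np.zeros(mask.shape)
        vol[mask] = deg
        zmaps[o.obs_id] = fm.z_standardize(vol, mask)

    pat_ids = [o.obs_id for o in cohort.patients if o.obs_id in zmaps]
    con_ids = [o.obs_id for o in cohort.controls if o.obs_id in zmaps]
    pat = np.stack([zmaps[i] for i in pat_ids])
    con = np.stack([zmaps[i] for i in con_ids])
    tmap, residuals = ci.group_t_map(
        pat, con, mask, variant=config.group_t_variant
    )
    fwhm = ci.estimate_fwhm(residuals, mask, vox)
    try:
        fwhm_mm = fwhm.mean_fwhm_mm
    except DegenerateInputError:
        fwhm_mm = 0.0
    sim = ci.alphasim_min_cluster(
        mask, fwhm_mm, config.degree_voxel_p, vox,
        alpha=config.degree_alpha,
        n_iterations=config.alphasim_iterations,
        connectivity=config.connectivity,
        seed=config.rng_seed + 202,
    )
    from scipy import stats as sps

    df = len(pat_ids) + len(con_ids) - 2
    tthr = float(sps.t.isf(config.degree_voxel_p / 2.0, df))
    table = ci.extract_clusters(
        tmap, mask, tthr, sim.min_cluster_voxels,
        connectivity=config.connectivity, affine=cohort.affine,
    )
    significant = len(table) > 0
    if significant:
        primary = max(table.clusters, key=lambda c: abs(c.peak_stat))
        peak_mask = table.labels == primary.label
    else:
        primary = None
        peak_mask = None  # fall back to the global peak within the mask
    seed = fm.seed_from_peak(
        np.where(np.isfinite(tmap), tmap, 0.0), mask, cohort.affine,
        radius_mm=config.seed_radius_mm, peak_mask=peak_mask,
    )
    seed_mask = seed.mask(mask.shape)
    seed_degree = {
        oid: float(zmaps[oid][seed_mask].mean()) for oid in pat_ids
    }
    scores = [composites[oid] for oid in pat_ids]
    beh = st.pearson_r([seed_degree[oid] for oid in pat_ids], scores)
    log.info(
        "degree: %d clusters (significant=%s), seed %d voxels, r=%.3f",
        len(table), significant, len(seed.voxels), beh.r,
    )
    return {
        "z_degree_maps": zmaps,
        "t_map": tmap,
        "fwhm_mm": fwhm.fwhm_mm,
        "alphasim": sim.to_dict(),
        "voxel_t_threshold": tthr,
        "clusters": [dataclasses.asdict(c) for c in table],
        "cluster_significant": significant,
        "cluster_labels": table.labels,
        "seed": {
            "center_mm": seed.center_mm,
            "radius_mm": seed.radius_mm,
            "voxels": [list(v) for v in seed.voxels],
        },
        "seed_obj": seed,
        "patient_ids": pat_ids,
        "control_ids": con_ids,
        "seed_degree": seed_degree,
        "behavior_correlation": _corr_dict(beh),
    }


# ---------------------------------------------------------------------------
# stage: seed FC -> behavior
# ---------------------------------------------------------------------------

def _seed_fc_stage(
    cohort: synth.Cohort,
    config: PipelineConfig,
    mask: np.ndarray,
    prep: dict,
    seed: fm.Seed,
    pat_ids: list,
    composites: dict,
) -> dict:
    vox = [config.synthetic.voxel_mm] * 3
    zmaps = []
    for oid in pat_ids:
        entry = prep[oid]
        bold = _series_to_bold(entry, mask, cohort.config.tr_s, cohort.affine)
        zmaps.append(fm.seed_fc_zmap(bold, seed, mask))
    zmaps = np.stack(zmaps)
    scores = np.array([composites[oid] for oid in pat_ids])

    rmap, df = fm.map_behavior_correlation(zmaps, scores, mask)
    finite = np.isfinite(rmap) & mask
    rthr = fm.r_threshold_for_p(config.fc_voxel_p, df)

    # smoothness from the per-voxel residuals of the map ~ score regression
    yc = scores - scores.mean()
    denom = float(yc @ yc)
    flat = np.where(np.isfinite(zmaps), zmaps, 0.0).reshape(len(pat_ids), -1)
    slope = (flat * yc[:, None]).sum(axis=0) / denom
    resid = flat - flat.mean(axis=0) - np.outer(yc, slope)
    residuals = resid.reshape(zmaps.shape)
    try:
        fwhm = ci.estimate_fwhm(residuals, finite, vox)
        fwhm_mm = fwhm.mean_fwhm_mm
        fwhm_axes = fwhm.fwhm_mm
    except DegenerateInputError:
        fwhm_mm, fwhm_axes = 0.0, (0.0, 0.0, 0.0)
    sim = ci.alphasim_min_cluster(
        finite, fwhm_mm, config.fc_voxel_p, vox,
        alpha=config.fc_alpha,
        n_iterations=config.alphasim_iterations,
        connectivity=config.connectivity,
        seed=config.rng_seed + 303,
    )
    table = ci.extract_clusters(
        rmap, finite, rthr, sim.min_cluster_voxels,
        connectivity=config.connectivity, affine=cohort.affine,
    )
    cluster_values = {}
    for c in table:
        cmask = table.labels == c.label
        cluster_values[c.label] = np.array(
            [float(np.nanmean(z[cmask])) for z in zmaps]
        )
    log.info("seed FC: %d surviving clusters", len(table))
    return {
        "z_maps": zmaps,
        "r_map": rmap,
        "df": df,
        "voxel_r_threshold": rthr,
        "fwhm_mm": fwhm_axes,
        "alphasim": sim.to_dict(),
        "clusters": [dataclasses.asdict(c) for c in table],
        "cluster_labels": table.labels,
        "n_clusters": len(table),
        "cluster_values": cluster_values,
    }


# ---------------------------------------------------------------------------
# validation / specificity (spec-level operations, reusable standalone)
# ---------------------------------------------------------------------------

def validate_with_covariates(
    cluster_values: np.ndarray,
    scores: np.ndarray,
    covariates: pd.DataFrame,
    first_obs_mask: np.ndarray | None = None,
) -> list:
    """Raw r, single-covariate partials, all-covariate partial, and the
    first-observation-subset raw r, for one column of cluster values."""
    rows = [CorrelationRow("raw", st.pearson_r(cluster_values, scores))]
    for name in covariates.columns:
        rows.append(
            CorrelationRow(
                f"partial:{name}",
                st.partial_r(
                    cluster_values, scores,
                    covariates[[name]].to_numpy(), [name],
                ),
            )
        )
    rows.append(
        CorrelationRow(
            "partial:all",
            st.partial_r(
                cluster_values, scores,
                covariates.to_numpy(), list(covariates.columns),
            ),
        )
    )
    if first_obs_mask is not None and first_obs_mask.sum() >= 3:
        rows.append(
            CorrelationRow(
                "first_observations",
                st.pearson_r(
                    cluster_values[first_obs_mask], scores[first_obs_mask]
                ),
            )
        )
    return rows


def specificity_test(
    cluster_values: np.ndarray,
    semantic_scores: np.ndarray,
    nonsemantic_scores: dict,
) -> dict:
    """Correlations with each non-semantic score, plus the semantic
    correlation partialling out all non-semantic scores."""
    out = {}
    for name, vals in nonsemantic_scores.items():
        out[f"nonsemantic:{name}"] = _corr_dict(
            st.pearson_r(cluster_values, np.asarray(vals))
        )
    cov = np.column_stack([np.asarray(v) for v in nonsemantic_scores.values()])
    try:
        partial = st.partial_r(
            cluster_values, semantic_scores, cov, list(nonsemantic_scores)
        )
        out["semantic_partial_nonsemantic"] = _corr_dict(partial)
    except DegenerateInputError:
        out["semantic_partial_nonsemantic"] = {"r": None, "flag": "degenerate"}
    return out


def _validation_stage(
    cohort: synth.Cohort,
    config: PipelineConfig,
    behavior: dict,
    atrophy: dict,
    degree: dict,
    seed_fc: dict,
    prep: dict,
) -> dict:
    pat_ids = degree["patient_ids"]
    composites = behavior["composite_by_obs"]
    scores = np.array([composites[oid] for oid in pat_ids])
    obs_by_id = {o.obs_id: o for o in cohort.observations}
    seed_mask = degree["seed_obj"].mask(cohort.brain_mask.shape)
    prep_mfalff = {
        oid: entry["mfalff"] for oid, entry in prep.items() if entry is not None
    }

    cov = pd.DataFrame(
        {
            "total_gmv": [
                float(atrophy["smoothed_gmv"][oid][cohort.brain_mask].sum())
                for oid in pat_ids
            ],
            "seed_gmv": [
                float(atrophy["smoothed_gmv"][oid][seed_mask].sum())
                for oid in pat_ids
            ],
            "seed_mfalff": [
                float(prep_mfalff[oid][seed_mask].sum()) for oid in pat_ids
            ],
            "observation_index": [
                obs_by_id[oid].obs_index for oid in pat_ids
            ],
        },
        index=pat_ids,
    )
    first_obs = np.array([obs_by_id[oid].obs_index == 1 for oid in pat_ids])
    nonsem = {
        task: np.array(
            [behavior["corrected"][oid][task].t_value for oid in pat_ids]
        )
        for task in synth.NONSEMANTIC_TASKS
    }

    tables = {}
    for label, vals in seed_fc["cluster_values"].items():
        rows = validate_with_covariates(vals, scores, cov, first_obs)
        tables[int(label)] = {
            "validation": [r.to_dict() for r in rows],
            "specificity": specificity_test(vals, scores, nonsem),
        }
    return {
        "covariates": cov.to_dict(orient="list"),
        "covariate_labels": list(COVARIATE_LABELS),
        "first_observation_n": int(first_obs.sum()),
        "fc_cluster_tables": tables,
        "nonsemantic_tasks": list(synth.NONSEMANTIC_TASKS),
    }


# ---------------------------------------------------------------------------
# stage: structural tract analysis
# ---------------------------------------------------------------------------

def _tract_stage(
    cohort: synth.Cohort,
    config: PipelineConfig,
    degree: dict,
    seed_fc: dict,
    behavior: dict,
    validation: dict,
) -> dict:
    gtab = dw.GradientTable(bvecs=cohort.bvecs, bvals=cohort.bvals)
    brain = cohort.brain_mask

    tensors = {}
    fa_maps = {}
    ldh_maps = {}
    for o in cohort.observations:
        tf = dw.fit_tensor(o.dwi.astype(np.float64), gtab, brain)
        tensors[o.obs_id] = tf
        fa_maps[o.obs_id] = tf.fa
        ldh_maps[o.obs_id] = dw.ldh_map(o.dwi.astype(np.float64), gtab, brain)

    # seed region for tracking: the disconnected cluster if one survived,
    # otherwise the spherical seed
    if degree["cluster_significant"]:
        primary = max(
            degree["clusters"], key=lambda c: abs(c["peak_stat"])
        )
        region = degree["cluster_labels"] == primary["label"]
    else:
        region = degree["seed_obj"].mask(brain.shape)
    seed_voxels = [tuple(v) for v in np.argwhere(region)]

    control_ids = [o.obs_id for o in cohort.controls]
    streamlines = {}
    for i, oid in enumerate(control_ids):
        streamlines[oid] = dw.fact_track(
            tensors[oid], seed_voxels,
            seeds_per_voxel=config.seeds_per_voxel,
            angle_max_deg=config.angle_max_deg,
            fa_min=config.fa_min,
            rng_seed=config.rng_seed + 404 + i,
        )

    pat_ids = degree["patient_ids"]
    composites = behavior["composite_by_obs"]
    scores = np.array([composites[oid] for oid in pat_ids])
    cov = pd.DataFrame(validation["covariates"], index=pat_ids)

    tract_results = []
    integrity_correlations = []
    for c in seed_fc["clusters"]:
        cmask = seed_fc["cluster_labels"] == c["label"]
        subject_masks = [
            dw.tract_mask_between(streamlines[oid], region, cmask)
            for oid in control_ids
        ]
        group = dw.group_count_mask(subject_masks, config.tract_min_subjects)
        entry = {
            "fc_cluster_label": int(c["label"]),
            "n_subjects_with_streamlines": int(
                sum(m.mask.any() for m in subject_masks)
            ),
            "tract_voxels": int(group.mask.sum()),
            "tract_mm3": float(
                group.mask.sum() * config.synthetic.voxel_mm ** 3
            ),
        }
        if not group.mask.any():
            entry["connected"] = False
            tract_results.append(entry)
            continue
        entry["connected"] = True
        stats_by_obs = {
            o.obs_id: dw.tract_integrity(
                group, fa_maps[o.obs_id], ldh_maps[o.obs_id]
            )
            for o in cohort.observations
        }
        pat_fa = np.array([stats_by_obs[i].mean_fa for i in pat_ids])
        con_fa = np.array([stats_by_obs[i].mean_fa for i in control_ids])
        pat_ldh = np.array([stats_by_obs[i].mean_ldh for i in pat_ids])
        con_ldh = np.array([stats_by_obs[i].mean_ldh for i in control_ids])
        for name, pv, cv in (("fa", pat_fa, con_fa), ("ldh", pat_ldh, con_ldh)):
            entry[f"{name}_group_welch_t"] = st.welch_t(
                pv.mean(), pv.std(ddof=1), pv.size,
                cv.mean(), cv.std(ddof=1), cv.size,
            )[0]
            entry[f"{name}_group_pooled_t"] = st.student_t_pooled(
                pv.mean(), pv.std(ddof=1), pv.size,
                cv.mean(), cv.std(ddof=1), cv.size,
            )[0]
            corr = {
                "index": name,
                "fc_cluster_label": int(c["label"]),
                "semantic": _corr_dict(st.pearson_r(pv, scores)),
                "semantic_partial_all": _corr_dict(
                    st.partial_r(pv, scores, cov.to_numpy(), list(cov.columns))
                ),
            }
            integrity_correlations.append(corr)
        tract_results.append(entry)
    log.info("tract: %d FC clusters examined", len(tract_results))
    return {
        "tracts": tract_results,
        "integrity_correlations": integrity_correlations,
        "n_tracking_subjects": len(control_ids),
    }


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig, cohort: synth.Cohort | None = None
) -> ResultsBundle:
    """Run the full analysis sequence and return the results bundle."""
    if cohort is None:
        cohort = synth.generate_cohort(config.synthetic)

    behavior = _behavior_stage(cohort)
    atrophy = _atrophy_stage(cohort, config)
    mask = atrophy["mask"]

    prep = _preprocess_bold(cohort, config, mask)

    degree = _degree_stage(
        cohort, config, mask, prep, behavior["composite_by_obs"]
    )
    seed_fc = _seed_fc_stage(
        cohort, config, mask, prep, degree["seed_obj"],
        degree["patient_ids"], behavior["composite_by_obs"],
    )
    validation = _validation_stage(
        cohort, config, behavior, atrophy, degree, seed_fc, prep
    )
    tract = (
        _tract_stage(cohort, config, degree, seed_fc, behavior, validation)
        if config.run_structural
        else {"skipped": True, "integrity_correlations": []}
    )

    maps = {
        "atrophy_t": (atrophy["t_map"], cohort.affine),
        "atrophy_mask": (mask, cohort.affine),
        "degree_t": (degree["t_map"], cohort.affine),
        "fc_behavior_r": (seed_fc["r_map"], cohort.affine),
    }
    behavior_out = {
        "group_tests": behavior["group_tests"],
        "composite_by_obs": behavior["composite_by_obs"],
        "corrected_t": {
            oid: {t: s.t_value for t, s in d.items()}
            for oid, d in behavior["corrected"].items()
        },
        "classification": {
            oid: {t: s.classification for t, s in d.items()}
            for oid, d in behavior["corrected"].items()
        },
        "n_patient_observations": behavior["n_patient_observations"],
        "n_controls": behavior["n_controls"],
    }
    atrophy_out = {
        k: atrophy[k]
        for k in ("fwhm_mm", "alphasim", "voxel_t_threshold", "clusters")
    }
    atrophy_out["mask_voxels"] = int(mask.sum())
    degree_out = {
        k: degree[k]
        for k in (
            "fwhm_mm", "alphasim", "voxel_t_threshold", "clusters",
            "cluster_significant", "seed", "seed_degree",
            "behavior_correlation", "patient_ids", "control_ids",
        )
    }
    seed_fc_out = {
        k: seed_fc[k]
        for k in (
            "df", "voxel_r_threshold", "fwhm_mm", "alphasim", "clusters",
            "n_clusters",
        )
    }
    seed_fc_out["cluster_values"] = {
        int(k): v.tolist() for k, v in seed_fc["cluster_values"].items()
    }

    bundle = ResultsBundle(
        config=config,
        behavior=behavior_out,
        atrophy=atrophy_out,
        degree=degree_out,
        seed_fc=seed_fc_out,
        validation=validation,
        tract=tract,
        maps=maps,
    )
    # keep heavyweight internals available to callers that need them
    bundle.maps["degree_seed_obj"] = degree["seed_obj"]
    bundle.maps["seed_fc_labels"] = (seed_fc["cluster_labels"], cohort.affine)
    bundle.maps["degree_labels"] = (degree["cluster_labels"], cohort.affine)
    return bundle


# ---------------------------------------------------------------------------
# persistence / report
# ---------------------------------------------------------------------------

def save_results(bundle: ResultsBundle, outdir) -> dict:
    """Write all artifacts plus a manifest; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"artifacts": []}

    def record(path, stage):
        manifest["artifacts"].append({"path": str(path.name), "stage": stage})

    for name, value in bundle.maps.items():
        if name == "degree_seed_obj":
            continue
        arr, affine = value
        path = out / f"{name}.nii.gz"
        save_volume(np.nan_to_num(np.asarray(arr, dtype=float)), affine, path)
        record(path, name.split("_")[0])
    results_path = out / "results.json"
    save_json(bundle.to_dict(), results_path)
    record(results_path, "all")
    seed = bundle.maps.get("degree_seed_obj")
    if seed is not None:
        seed_path = out / "seed.json"
        save_json(
            {
                "center_mm": list(seed.center_mm),
                "radius_mm": seed.radius_mm,
                "voxels": [list(v) for v in seed.voxels],
            },
            seed_path,
        )
        record(seed_path, "degree")
    report_path = out / "report.md"
    report_path.write_text(write_report(bundle))
    record(report_path, "all")
    save_json(manifest, out / "manifest.json")
    return manifest


def write_report(bundle: ResultsBundle) -> str:
    """Markdown report; the header lists every stage threshold verbatim."""
    c = bundle.config
    lines = [
        "# Network-behavior mapping report",
        "",
        "## Settings",
        f"- FC threshold r > {c.r_threshold}",
        f"- seed radius {c.seed_radius_mm} mm",
        f"- atrophy: voxel p {c.atrophy_voxel_p}, corrected alpha {c.atrophy_alpha}",
        f"- degree: voxel p {c.degree_voxel_p}, corrected alpha {c.degree_alpha}",
        f"- seed FC: voxel p {c.fc_voxel_p}, corrected alpha {c.fc_alpha}",
        f"- smoothing FWHM: {c.smooth_fwhm_gmv_mm} mm (GMV), "
        f"{c.smooth_fwhm_bold_mm} mm (BOLD)",
        f"- band-pass {c.band_hz[0]}-{c.band_hz[1]} Hz",
        f"- Monte-Carlo iterations {c.alphasim_iterations}, "
        f"connectivity {c.connectivity}",
        f"- rng seed {c.rng_seed}",
        "",
        "## Behavioral group tests (Welch and pooled t per task)",
    ]
    for task, row in bundle.behavior["group_tests"].items():
        lines.append(
            f"- {task}: welch t = {row['welch_t']:.2f}, "
            f"pooled t = {row['pooled_t']:.2f}"
        )
    lines += [
        "",
        "## Atrophy network",
        f"- mask voxels: {bundle.atrophy['mask_voxels']}",
        f"- min cluster size: {bundle.atrophy['alphasim']['min_cluster_voxels']}",
        f"- clusters: {len(bundle.atrophy['clusters'])}",
        "",
        "## Degree centrality contrast",
        f"- significant cluster: {bundle.degree['cluster_significant']}",
        f"- seed center (mm): {bundle.degree['seed']['center_mm']}",
        f"- degree-behavior r = "
        f"{bundle.degree['behavior_correlation']['r']:.3f} "
        f"(p = {bundle.degree['behavior_correlation']['p']:.4f}, "
        f"n = {bundle.degree['behavior_correlation']['n']})",
        "",
        "## Seed FC behavior clusters",
        f"- surviving clusters: {bundle.seed_fc['n_clusters']}",
    ]
    for cl in bundle.seed_fc["clusters"]:
        lines.append(
            f"  - label {cl['label']}: {cl['size_voxels']} voxels "
            f"({cl['size_mm3']:.0f} mm3), peak r = {cl['peak_stat']:.3f} "
            f"at {cl['peak_mm']}"
        )
    if bundle.tract.get("skipped"):
        lines += ["", "## Structural analysis", "- skipped"]
    else:
        lines += ["", "## Structural analysis"]
        for tr in bundle.tract.get("tracts", []):
            lines.append(
                f"- FC cluster {tr['fc_cluster_label']}: connected = "
                f"{tr['connected']}, tract voxels = {tr['tract_voxels']}"
            )
        for row in bundle.tract.get("integrity_correlations", []):
            lines.append(
                f"  - {row['index']} vs semantic: r = "
                f"{row['semantic']['r']:.3f} (p = {row['semantic']['p']:.4f})"
            )
    lines.append("")
    return "\n".join(lines)
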