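"""Scalar statistics used throughout the pipeline.

Single-case standardization against a small control sample, behavioral
composites, two-sample tests from summary statistics, (partial) correlation,
the Fisher transform, a 2x2 contingency test, and the diagnostic
classification rule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateInputError,
    IncompleteProfileError,
    InsufficientDataError,
    SaturationError,
)

__all__ = [
    "ControlSample",
    "CorrectedScore",
    "CompositeScore",
    "CorrelationResult",
    "crawford_howell_t",
    "composite_semantic",
    "welch_t",
    "student_t_pooled",
    "pearson_r",
    "partial_r",
    "fisher_z",
    "pearson_chi2",
    "classify_sd_diagnosis",
    "CORE_NAMING_TASKS",
    "CORE_COMPREHENSION_TASKS",
    "OTHER_FEATURE_DIRECTIONS",
]

DEFAULT_CUTOFF = -1.96


@dataclass(frozen=True)
class ControlSample:
    """Summary of a control group's score distribution on one task.

    ``sd`` uses the sample (n-1) denominator.
    """

    n: int
    mean: float
    sd: float
    values: tuple = ()

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError(
                f"control sample needs n >= 2, got n={self.n}"
            )
        if not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise DegenerateInputError("control summary must be finite")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "ControlSample":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise InsufficientDataError(
                f"control sample needs n >= 2, got n={arr.size}"
            )
        return cls(
            n=int(arr.size),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
            values=tuple(float(v) for v in arr),
        )


@dataclass(frozen=True)
class CorrectedScore:
    """Single-case standardized score with its impaired/spared label."""

    task_id: str
    t_value: float
    p_value: float
    df: int
    classification: str  # "impaired" | "spared" | "indeterminate"
    cutoff: float = DEFAULT_CUTOFF


@dataclass(frozen=True)
class CompositeScore:
    observation_id: str
    value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    n: int
    covariate_labels: tuple = ()


def crawford_howell_t(
    patient_score: float,
    controls: ControlSample,
    task_id: str = "",
    cutoff: float = DEFAULT_CUTOFF,
) -> CorrectedScore:
    """Standardize a single patient score against a small control sample.

    t = (x - mean) / (sd * sqrt((n + 1) / n)), df = n - 1; two-sided p.
    Classification: impaired if t < cutoff, spared if t > cutoff,
    indeterminate only at an exact tie.
    """
    if controls.sd <= 0:
        raise DegenerateInputError(
            "control sd must be > 0 for single-case standardization"
        )
    n = controls.n
    t = (patient_score - controls.mean) / (controls.sd * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    # dichotomy at the cutoff: lower -> impaired, higher -> spared;
    # only an exact tie is indeterminate
    if t < cutoff:
        cls = "impaired"
    elif t > cutoff:
        cls = "spared"
    else:
        cls = "indeterminate"
    return CorrectedScore(
        task_id=task_id, t_value=float(t), p_value=float(p), df=df,
        classification=cls, cutoff=cutoff,
    )


def composite_semantic(
    corrected_t_by_task: np.ndarray,
    observation_ids: Sequence[str] | None = None,
) -> list[CompositeScore]:
    """Average per-task z-scores (sample sd) into one composite per row.

    ``corrected_t_by_task`` is observations x tasks. Composites are centered
    by construction: they sum to zero across the standardization set.
    """
    x = np.asarray(corrected_t_by_task, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D observations x tasks array")
    n, _ = x.shape
    if n < 2:
        raise InsufficientDataError("need >= 2 observations for z-transform")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = np.nonzero(sds <= 0)[0].tolist()
        raise DegenerateInputError(f"constant task column(s): {bad}")
    z = (x - x.mean(axis=0)) / sds
    values = z.mean(axis=1)
    if observation_ids is None:
        observation_ids = [str(i) for i in range(n)]
    return [
        CompositeScore(observation_id=oid, value=float(v))
        for oid, v in zip(observation_ids, values)
    ]


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Unequal-variance two-sample t with Welch-Satterthwaite df."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("welch_t needs n >= 2 per group")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        raise DegenerateInputError("both group sds are zero")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df)


def student_t_pooled(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t, df = n1 + n2 - 2."""
    if n1 + n2 < 3 or min(n1, n2) < 1:
        raise InsufficientDataError("student_t_pooled needs n1 + n2 >= 3")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        raise DegenerateInputError("pooled variance is zero")
    t = (mean1 - mean2) / (np.sqrt(sp2) * np.sqrt(1 / n1 + 1 / n2))
    return float(t), float(df)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    # relative tolerance so numerically-zero residual vectors are caught
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max(initial=0.0)))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max(initial=0.0)))
    if nx <= tol_x or ny <= tol_y:
        raise DegenerateInputError("constant input to correlation")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _r_to_p(r: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with df = n - 2 and a two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise InsufficientDataError("pearson_r needs n >= 3")
    r = _pearson(x, y)
    df = x.size - 2
    return CorrelationResult(r=r, df=df, p=_r_to_p(r, df), n=x.size)


def partial_r(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    covariate_labels: Sequence[str] | None = None,
) -> CorrelationResult:
    """Correlation of x and y after residualizing both on the covariates.

    Both variables are regressed (least squares, with intercept) on the
    covariate columns; the residuals are correlated. df = n - 2 - q.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        base = pearson_r(x, y)
        return CorrelationResult(
            r=base.r, df=base.df, p=base.p, n=base.n, covariate_labels=()
        )
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n, q = c.shape
    if x.size != n or y.size != n:
        raise ValueError("covariates must have one row per observation")
    if n <= 2 + q:
        raise InsufficientDataError(
            f"partial_r needs n > 2 + q (n={n}, q={q})"
        )
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("covariate design is rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = _pearson(rx, ry)
    df = n - 2 - q
    labels = tuple(covariate_labels) if covariate_labels else tuple(
        f"c{i}" for i in range(q)
    )
    return CorrelationResult(
        r=r, df=df, p=_r_to_p(r, df), n=n, covariate_labels=labels
    )


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, atanh(r); requires |r| < 1."""
    if abs(r) >= 1.0:
        raise SaturationError(f"|r| must be < 1, got {r}")
    return float(np.arctanh(r))


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise DegenerateInputError("empty row or column margin")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


# Task sets for the diagnostic rule. Core: both naming tasks impaired, all
# three comprehension tasks impaired, plus the anterior-temporal atrophy
# criterion. Other features carry the direction that counts toward the rule.
CORE_NAMING_TASKS = ("oral_picture_naming", "oral_sound_naming")
CORE_COMPREHENSION_TASKS = (
    "picture_associative_matching",
    "word_associate_matching",
    "word_picture_verification",
)
OTHER_FEATURE_DIRECTIONS: Mapping[str, str] = {
    "surface_dyslexia": "impaired",
    "object_knowledge": "impaired",
    "repetition": "spared",
    "speech_production": "spared",
}


def classify_sd_diagnosis(
    corrected: Mapping[str, CorrectedScore],
    atl_gmv: float,
    control_atl: ControlSample,
    min_other_features: int = 3,
) -> dict:
    """Evaluate the diagnostic rule on a profile of corrected scores.

    Core criteria: impaired on both naming tasks, impaired on all three
    comprehension tasks, and anterior-temporal gray-matter volume strictly
    below control mean - 2*sd. A case additionally needs at least
    ``min_other_features`` of the four other features in their stated
    direction.
    """
    required = CORE_NAMING_TASKS + CORE_COMPREHENSION_TASKS
    missing = [t for t in required if t not in corrected]
    if missing:
        raise IncompleteProfileError(f"missing core tasks: {missing}")
    present_other = [t for t in OTHER_FEATURE_DIRECTIONS if t in corrected]
    if len(present_other) < 4:
        raise IncompleteProfileError(
            "all four other diagnostic features must be scored"
        )

    naming_impaired = all(
        corrected[t].classification == "impaired" for t in CORE_NAMING_TASKS
    )
    comprehension_impaired = all(
        corrected[t].classification == "impaired"
        for t in CORE_COMPREHENSION_TASKS
    )
    atrophy = atl_gmv < control_atl.mean - 2.0 * control_atl.sd

    other_met = {
        t: corrected[t].classification == want
        for t, want in OTHER_FEATURE_DIRECTIONS.items()
    }
    n_other = sum(other_met.values())

    return {
        "naming_impaired": naming_impaired,
        "comprehension_impaired": comprehension_impaired,
        "anterior_temporal_atrophy": atrophy,
        "other_features_met": other_met,
        "n_other_features": n_other,
        "meets_criteria": bool(
            naming_impaired
            and comprehension_impaired
            and atrophy
            and n_other >= min_other_features
        ),
    }
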