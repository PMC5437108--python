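"""File I/O helpers: NIfTI volumes, gradient tables, behavior tables, JSON."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NetbehError

__all__ = [
    "save_volume",
    "load_volume",
    "load_bvecs_bvals",
    "save_bvecs_bvals",
    "load_behavior_table",
    "save_behavior_table",
    "save_json",
    "load_json",
]

BEHAVIOR_COLUMNS = [
    "observation_id", "patient_id", "group", "obs_index", "task_id", "raw_score",
]


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    import nibabel as nib

    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata()), np.asarray(img.affine)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise NetbehError(f"cannot read NIfTI volume {path}: {exc}") from exc


def save_bvecs_bvals(bvecs: np.ndarray, bvals: np.ndarray, stem) -> None:
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.8f")
    np.savetxt(stem.with_suffix(".bval"), np.asarray(bvals)[None], fmt="%.2f")


def load_bvecs_bvals(bvec_path, bval_path) -> tuple[np.ndarray, np.ndarray]:
    try:
        bvecs = np.loadtxt(bvec_path)
        bvals = np.loadtxt(bval_path)
    except Exception as exc:  # noqa: BLE001
        raise NetbehError(
            f"cannot read gradient files {bvec_path} / {bval_path}: {exc}"
        ) from exc
    if bvecs.ndim != 2:
        raise NetbehError(f"malformed bvec file {bvec_path}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    bvals = np.atleast_1d(bvals)
    if bvecs.shape[0] != bvals.size:
        raise NetbehError(
            f"bvec/bval length mismatch: {bvecs.shape[0]} vs {bvals.size}"
        )
    return bvecs, bvals


def save_behavior_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_behavior_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise NetbehError(f"cannot read behavior table {path}: {exc}") from exc
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise NetbehError(
            f"behavior table {path} missing columns {missing}"
        )
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def load_json(path):
    try:
        return json.loads(Path(path).read_text())
    except Exception as exc:  # noqa: BLE001
        raise NetbehError(f"cannot read JSON {path}: {exc}") from exc
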