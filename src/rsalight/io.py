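"""NIfTI / TSV / JSON readers and writers for all pipeline artefacts."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

EVENT_COLUMNS = ("onset", "duration", "trial_type")


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_nifti(path, data: np.ndarray, affine: np.ndarray | None = None,
                voxel_size: float = 1.0) -> Path:
    path = Path(path)
    if affine is None:
        affine = _affine(voxel_size)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
    return path


def read_nifti(path):
    """Return (data, affine, header summary) for a 3-D or 4-D NIfTI file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # corrupt header / truncated file
        raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise IOError(f"{path}: expected 3-D or 4-D image, got {data.ndim}-D")
    summary = {
        "shape": tuple(int(s) for s in data.shape),
        "voxel_sizes": tuple(float(z) for z in img.header.get_zooms()[:3]),
    }
    return data, img.affine, summary


def write_events(path, events: pd.DataFrame) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events(path) -> pd.DataFrame:
    """Validated BIDS-style events table (onset/duration/trial_type [...]).

    Rows are re-sorted by onset (with a warning) when out of order;
    duplicate overlapping onsets are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing events columns {missing}")
    if (df["duration"] <= 0).any():
        raise ValueError(f"{path}: durations must be positive")
    if not df["onset"].is_monotonic_increasing:
        warnings.warn(f"{path}: onsets out of order; re-sorting")
        df = df.sort_values("onset", ignore_index=True)
    if df["onset"].duplicated().any():
        raise ValueError(f"{path}: duplicate onsets (overlapping trials)")
    return df


def write_participants(path, records: pd.DataFrame) -> Path:
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: participants table needs subject_id and group")
    if df["group"].isna().any():
        raise ValueError(f"{path}: group must be non-missing for every subject")
    return df


def _sidecar(path: Path) -> Path:
    if path.suffix == ".gz":
        path = path.with_suffix("")
    return path.with_suffix(".json")


def write_beta_stack(path, stack, voxel_size: float = 1.0) -> Path:
    """4-D NIfTI (trial axis last) plus a JSON sidecar with trial metadata."""
    path = Path(path)
    write_nifti(path, np.moveaxis(stack.data, 0, -1), voxel_size=voxel_size)
    sidecar = _sidecar(path)
    meta = {
        "subject_id": stack.subject_id,
        "condition": stack.condition,
        "n_trials": int(stack.n_trials),
        "events": stack.events.to_dict(orient="list"),
        "flat_voxels": [int(v) for v in stack.flat_voxels],
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_beta_stack(path):
    from .glm import BetaStack

    path = Path(path)
    data, _, _ = read_nifti(path)
    sidecar = _sidecar(path)
    meta = json.loads(sidecar.read_text())
    data = np.moveaxis(data, -1, 0)
    return BetaStack(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        data=data,
        mask=np.ones(data.shape[1:], dtype=bool),
        events=pd.DataFrame(meta["events"]),
        flat_voxels=meta.get("flat_voxels", []),
    )


def write_similarity_map(path, sim_map, voxel_size: float = 1.0) -> Path:
    path = Path(path)
    write_nifti(path, np.nan_to_num(sim_map.data, nan=0.0), voxel_size=voxel_size)
    sidecar = _sidecar(path)
    sidecar.write_text(json.dumps({
        "subject_id": sim_map.subject_id,
        "condition": sim_map.condition,
        "radius_voxels": int(sim_map.radius_voxels),
        "n_trials": int(sim_map.n_trials),
        "n_dropped_pairs": int(sim_map.n_dropped_pairs),
    }, indent=1))
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
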