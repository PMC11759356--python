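"""File I/O: TSV time-course tables with JSON sidecars, NIfTI ingestion,
and long-format results tables.

Conventions: volume index is 0-based and seconds = index * TR; TSV files
carry a ``time`` column of volume indices plus one column per region or
sub-region, and a sidecar JSON (same stem, ``.json``) with participant,
group, run, condition and TR metadata.  Every results record carries
provenance (config hash, seed, stage).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_timecourses",
    "read_timecourses",
    "read_nifti_timecourses",
    "results_record",
    "config_hash",
    "REQUIRED_METADATA",
]

REQUIRED_METADATA = ("participant", "group", "run", "condition", "TR")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (provenance)."""
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_timecourses(values: np.ndarray, columns: list, meta: dict, path: str | Path) -> Path:
    """Write a (n_series, n_time) matrix as TSV (time x series) plus sidecar.

    The sidecar JSON holds the required metadata fields; round-trips
    losslessly with :func:`read_timecourses`.
    """
    path = Path(path)
    missing = [k for k in REQUIRED_METADATA if k not in meta]
    if missing:
        raise ValueError(f"metadata missing required fields: {missing}")
    values = np.asarray(values, float)
    df = pd.DataFrame(values.T, columns=list(columns))
    df.insert(0, "time", np.arange(values.shape[1]))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_timecourses(path: str | Path) -> tuple[np.ndarray, list, dict]:
    """Read a TSV time-course table and its JSON sidecar.

    Returns (values (n_series, n_time), column names, metadata).  Missing
    sidecar or metadata fields and NaN cells are errors naming the problem.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_METADATA if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing metadata fields: {missing}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path} has no 'time' column")
    data = df.drop(columns="time")
    if data.isna().any().any():
        bad = [
            (int(df.loc[i, "time"]), c)
            for c in data.columns
            for i in data.index[data[c].isna()]
        ]
        raise ValueError(f"NaN cells at (time, column): {bad[:10]}")
    return data.to_numpy().T, list(data.columns), meta


def read_nifti_timecourses(
    nifti_path: str | Path, label_path: str | Path
) -> tuple[np.ndarray, list]:
    """Region-mean time courses from a 4-D NIfTI and an integer label image.

    Voxels are averaged per nonzero integer label code (voxel ordering is the
    array's C order; irrelevant to the mean).  Returns
    (values (n_labels, n_time), label codes as strings).
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    lab = nib.load(str(label_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    labels = np.asanyarray(lab.dataobj).astype(int)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI, got shape {data.shape}")
    if labels.shape != data.shape[:3]:
        raise ValueError(
            f"label image shape {labels.shape} does not match volume shape {data.shape[:3]}"
        )
    codes = sorted(int(c) for c in np.unique(labels) if c != 0)
    out = np.stack([data[labels == c].mean(axis=0) for c in codes])
    return out, [str(c) for c in codes]


def results_record(
    stage: str,
    name: str,
    estimate: float,
    config: dict,
    seed: int,
    sem: float = np.nan,
    T: float = np.nan,
    p: float = np.nan,
    group: str = "",
    condition: str = "",
    flags: str = "",
) -> dict:
    """One long-format results row with provenance fields."""
    return {
        "stage": stage,
        "name": name,
        "group": group,
        "condition": condition,
        "estimate": estimate,
        "sem": sem,
        "T": T,
        "p": p,
        "flags": flags,
        "config_hash": config_hash(config),
        "seed": seed,
        "stage_version": "1",
    }
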