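"""Table and volume I/O for the state-space pipeline.

Parcel-resolved data travel as parcel-id-indexed TSV; probe ratings and
coordinates as CSV; configuration and model serializations as YAML.  A
NIfTI path exists for volumetric inputs: a 4-D (or 3-D) volume plus an
integer-labeled atlas on the same grid reduces to per-parcel means.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_parcel_table",
    "write_parcel_table",
    "read_nifti_parcellated",
    "read_events",
    "write_events",
    "config_hash",
]


class ParseError(ValueError):
    pass


def read_parcel_table(path) -> pd.DataFrame:
    """Read a parcel-indexed TSV (header column ``parcel_id``).

    Duplicate or missing parcel ids and non-numeric cells are rejected with
    the offending line named.
    """
    frame = pd.read_csv(path, sep="\t")
    if "parcel_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'parcel_id' header column")
    ids = frame["parcel_id"]
    if ids.isna().any():
        line = int(ids.index[ids.isna()][0]) + 2
        raise ParseError(f"{path}: missing parcel id at line {line}")
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        line = int(ids.index[ids.duplicated()][0]) + 2
        raise ParseError(f"{path}: duplicate parcel id {dup} at line {line}")
    frame = frame.set_index("parcel_id")
    value_cols = [c for c in frame.columns if c != "network"]
    for col in value_cols:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().sum() > frame[col].isna().sum():
            bad = frame.index[coerced.isna() & frame[col].notna()][0]
            line = int(np.where(frame.index == bad)[0][0]) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        frame[col] = coerced
    return frame


def write_parcel_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="parcel_id")


def read_nifti_parcellated(volume_path, atlas_path) -> pd.DataFrame:
    """Per-parcel means of a volume under an integer-labeled atlas.

    Label 0 is background.  The volume may be 3-D (one map) or 4-D (one
    column per frame).  Grids must match exactly (shape and affine).
    """
    vol = nib.load(str(volume_path))
    atlas = nib.load(str(atlas_path))
    if vol.shape[:3] != atlas.shape[:3] or not np.allclose(vol.affine, atlas.affine):
        raise ParseError("volume and atlas are not on the same voxel grid")
    labels = np.asarray(atlas.dataobj).astype(int)
    data = np.asarray(vol.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    ids = np.unique(labels)
    ids = ids[ids != 0]
    flat_labels = labels.ravel()
    out = np.empty((len(ids), data.shape[3]))
    for t in range(data.shape[3]):
        flat = data[..., t].ravel()
        sums = np.bincount(flat_labels, weights=flat)
        counts = np.bincount(flat_labels)
        out[:, t] = sums[ids] / counts[ids]
    cols = [f"map_{t + 1}" for t in range(data.shape[3])] if data.shape[3] > 1 else ["value"]
    return pd.DataFrame(out, index=pd.Index(ids, name="parcel_id"), columns=cols)


def read_events(path) -> pd.DataFrame:
    """BIDS-events-like TSV with onset/duration/event_type columns."""
    events = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "event_type"} - set(events.columns)
    if missing:
        raise ParseError(f"{path}: missing event columns {sorted(missing)}")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
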