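"""Readers and writers: NIfTI-1 volumes, CSV metadata, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import (
    GMDensityMap,
    GMMask,
    NormativeDatabase,
    SubjectMeta,
    VoxelGrid,
)

__all__ = [
    "read_gm_map",
    "write_gm_map",
    "read_mask",
    "write_mask",
    "read_metadata",
    "write_metadata",
    "assemble_ndb",
    "load_ndb",
    "write_json_report",
]

_SEX_ALIASES = {
    "m": "male", "male": "male",
    "f": "female", "female": "female",
    "": "unknown", "u": "unknown", "unknown": "unknown", "nan": "unknown",
}


def _subject_id_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def read_gm_map(path: str | Path, subject_id: str | None = None) -> GMDensityMap:
    """Read a 3-D GM density volume from a NIfTI-1 file.

    The grid (shape + affine) is taken from the header; values are cast to
    float64. The subject id defaults to the file name without extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {data.shape}")
    data = data.astype(float)
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    grid = VoxelGrid(data.shape, img.affine)
    return GMDensityMap(subject_id or _subject_id_from_path(path), data, grid)


def write_gm_map(map_: GMDensityMap, path: str | Path) -> None:
    img = nib.Nifti1Image(map_.values.astype(np.float64), map_.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> GMMask:
    path = Path(path)
    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3-D, got shape {data.shape}")
    return GMMask((data > 0).astype(np.uint8), VoxelGrid(data.shape, img.affine))


def write_mask(mask: GMMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    """Read subject metadata from CSV.

    Expected header: subject_id, age_years, sex, tiv_ml, scanner_id
    (the last two may be empty). Empty/unrecognized sex maps to "unknown".
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "scanner_id": str})
    required = {"subject_id", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in metadata: {dupes}")
    records = []
    for row in df.itertuples(index=False):
        age = pd.to_numeric(getattr(row, "age_years"))
        if pd.isna(age):
            raise ValueError(f"non-numeric age for subject {row.subject_id}")
        sex_raw = str(getattr(row, "sex", "") or "").strip().lower()
        sex = _SEX_ALIASES.get(sex_raw)
        if sex is None:
            raise ValueError(f"unrecognized sex {sex_raw!r} for subject {row.subject_id}")
        tiv = getattr(row, "tiv_ml", None)
        tiv = None if tiv is None or pd.isna(tiv) else float(tiv)
        scanner = getattr(row, "scanner_id", None)
        scanner = None if scanner is None or pd.isna(scanner) else str(scanner)
        records.append(
            SubjectMeta(
                subject_id=str(row.subject_id),
                age_years=float(age),
                sex=sex,
                tiv_ml=tiv,
                scanner_id=scanner,
            )
        )
    return records


def write_metadata(meta: Sequence[SubjectMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in meta],
            "age_years": [m.age_years for m in meta],
            "sex": [m.sex for m in meta],
            "tiv_ml": [m.tiv_ml for m in meta],
            "scanner_id": [m.scanner_id for m in meta],
        }
    ).to_csv(path, index=False)


def assemble_ndb(
    maps: Sequence[GMDensityMap],
    meta: Sequence[SubjectMeta],
    mask: GMMask,
) -> NormativeDatabase:
    """Assemble a normative database; canonical (sorted-by-id) ordering."""
    return NormativeDatabase(tuple(maps), tuple(meta), mask)


def load_ndb(ndb_dir: str | Path, meta_path: str | Path, mask_path: str | Path) -> NormativeDatabase:
    """Load an NDB from a directory of NIfTI maps + a metadata CSV + a mask.

    Map files must be named ``<subject_id>.nii`` or ``<subject_id>.nii.gz``.
    """
    ndb_dir = Path(ndb_dir)
    paths = sorted(list(ndb_dir.glob("*.nii")) + list(ndb_dir.glob("*.nii.gz")))
    if not paths:
        raise FileNotFoundError(f"no NIfTI files in {ndb_dir}")
    maps = [read_gm_map(p) for p in paths]
    return assemble_ndb(maps, read_metadata(meta_path), read_mask(mask_path))


def derive_gm_mask(ndb_maps: Sequence[GMDensityMap], threshold: float = 0.1) -> GMMask:
    """Derive a GM mask as {voxels where the mean GM density > threshold}.

    A stand-in for an externally supplied standard GM mask; the threshold
    excludes background and near-zero-variance voxels.
    """
    mean = np.mean([m.values for m in ndb_maps], axis=0)
    return GMMask((mean > threshold).astype(np.uint8), ndb_maps[0].grid)


def write_json_report(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
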