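"""Reading and writing pipeline artifacts.

Volumes (runs, parcellations, feature maps) go through NIfTI via nibabel,
with the voxel size carried in the affine and the repetition time in the
4th zoom.  Feature tables are tab-separated text with a ``subject`` and
``condition`` column followed by ``R001..Rnnn`` region columns.  Traces,
reports and ground truth are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import BoldRun, FeatureTable, Parcellation, VoxelMap

__all__ = [
    "save_run", "load_run", "save_parcellation", "load_parcellation",
    "save_map", "load_map", "save_feature_table", "load_feature_table",
    "save_json", "load_json",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    try:
        img = nib.load(path)
        img.get_fdata()  # force the read so truncation surfaces here
        return img
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc


def save_run(run: BoldRun, path: str | Path, voxel_size: float = 3.0) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data, _affine(voxel_size))
    img.header.set_zooms((voxel_size,) * 3 + (run.tr,))
    img.header["descrip"] = f"subject={run.subject_id};condition={run.condition}".encode()
    nib.save(img, path)
    return path


def load_run(path: str | Path, subject_id: str | None = None,
             condition: str | None = None) -> BoldRun:
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise IOError(f"{path}: expected a 4D volume, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3])
    desc = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    meta = dict(kv.split("=", 1) for kv in desc.split(";") if "=" in kv)
    return BoldRun(data=data, tr=tr,
                   subject_id=subject_id or meta.get("subject", "unknown"),
                   condition=condition or meta.get("condition", "unknown"))


def save_parcellation(parcellation: Parcellation, volume_path: str | Path,
                      table_path: str | Path) -> None:
    img = nib.Nifti1Image(parcellation.labels.astype(np.int32),
                          _affine(parcellation.voxel_size))
    nib.save(img, volume_path)
    pd.DataFrame(parcellation.region_table, columns=["label", "name"]).to_csv(
        table_path, sep="\t", index=False)


def load_parcellation(volume_path: str | Path, table_path: str | Path) -> Parcellation:
    img = _load_nifti(volume_path)
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    voxel_size = float(img.header.get_zooms()[0])
    df = pd.read_csv(table_path, sep="\t")
    table = list(zip(df["label"].astype(int), df["name"].astype(str)))
    return Parcellation(labels=labels, region_table=table, voxel_size=voxel_size)


def save_map(vmap: VoxelMap, path: str | Path, voxel_size: float = 3.0) -> Path:
    path = Path(path)
    data = np.where(vmap.mask, vmap.values, np.nan)
    img = nib.Nifti1Image(data, _affine(voxel_size))
    img.header["descrip"] = f"feature={vmap.feature_kind}".encode()
    nib.save(img, path)
    return path


def load_map(path: str | Path, feature_kind: str | None = None) -> VoxelMap:
    img = _load_nifti(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    desc = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
    meta = dict(kv.split("=", 1) for kv in desc.split(";") if "=" in kv)
    mask = np.isfinite(data)
    return VoxelMap(values=data, mask=mask,
                    feature_kind=feature_kind or meta.get("feature", "unknown"))


def save_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def load_feature_table(path: str | Path, feature_kind: str = "") -> FeatureTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise IOError(f"cannot read feature table {path}: {exc}") from exc
    for col in ("subject", "condition"):
        if col not in df.columns:
            raise IOError(f"{path}: missing required column {col!r}")
    region_cols = [c for c in df.columns if c.startswith("R") and c[1:].isdigit()]
    if not region_cols:
        raise IOError(f"{path}: no region columns (R001..) found")
    labels = [int(c[1:]) for c in region_cols]
    return FeatureTable(
        X=df[region_cols].to_numpy(dtype=np.float64),
        y=df["condition"].to_numpy(dtype=object),
        subject_id=df["subject"].astype(str).to_numpy(dtype=object),
        region_labels=labels, feature_kind=feature_kind,
    )


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_json(path: str | Path) -> dict:
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IOError(f"malformed JSON in {path} at line {exc.lineno}, "
                      f"column {exc.colno}: {exc.msg}") from exc
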