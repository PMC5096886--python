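"""Readers and writers: NIfTI volumes, TSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import Parcellation, VolumeGrid
from .qc_motion import MotionTrace
from .simulate import GroundTruth

__all__ = [
    "write_nifti",
    "read_nifti",
    "check_affines_match",
    "write_mask",
    "read_mask",
    "write_parcellation",
    "read_parcellation",
    "write_motion",
    "read_motion",
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "write_json",
    "read_json",
    "write_ground_truth",
    "read_ground_truth",
]


def write_nifti(path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), np.asarray(img.affine)


def check_affines_match(a: np.ndarray, b: np.ndarray, atol: float = 1e-4) -> None:
    """Hard error naming both affines when orientations disagree."""
    if not np.allclose(a, b, atol=atol):
        raise ValueError(
            f"affine mismatch between volumes:\n{np.asarray(a)}\nvs\n{np.asarray(b)}"
        )


def write_mask(path, grid: VolumeGrid) -> Path:
    return write_nifti(path, grid.mask.astype(np.uint8), grid.affine)


def read_mask(path) -> VolumeGrid:
    data, affine = read_nifti(path)
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return VolumeGrid(mask=data > 0, voxel_size=voxel_size, affine=affine)


def write_parcellation(path, parcellation: Parcellation) -> Path:
    """Integer label image plus a JSON sidecar (centroids, seed, exclusions)."""
    path = Path(path)
    write_nifti(path, parcellation.labels.astype(np.int32), parcellation.affine)
    sidecar = {
        "K": parcellation.K,
        "seed": parcellation.seed,
        "voxel_size": parcellation.voxel_size.tolist(),
        "centroids": np.asarray(parcellation.centroids, dtype=float).tolist(),
        "excluded_ids": sorted(parcellation.excluded_ids),
        "relabel_map": (
            {str(k): v for k, v in parcellation.relabel_map.items()}
            if parcellation.relabel_map
            else None
        ),
    }
    write_json(path.with_suffix("").with_suffix("") .as_posix() + ".json", sidecar)
    return path


def read_parcellation(path) -> Parcellation:
    path = Path(path)
    data, affine = read_nifti(path)
    sidecar = read_json(path.with_suffix("").with_suffix("").as_posix() + ".json")
    relabel = sidecar.get("relabel_map")
    return Parcellation(
        labels=np.asarray(data, dtype=np.int32),
        centroids=np.asarray(sidecar["centroids"], dtype=float),
        K=int(sidecar["K"]),
        voxel_size=np.asarray(sidecar["voxel_size"], dtype=float),
        affine=affine,
        seed=sidecar.get("seed"),
        excluded_ids=frozenset(sidecar.get("excluded_ids", [])),
        relabel_map={int(k): v for k, v in relabel.items()} if relabel else None,
    )


MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion(path, trace: MotionTrace) -> Path:
    df = pd.DataFrame(
        np.hstack([trace.translations, trace.rotations]), columns=MOTION_COLS
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_motion(path, repetition_time: float) -> MotionTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return MotionTrace(
        translations=df[MOTION_COLS[:3]].to_numpy(dtype=float),
        rotations=df[MOTION_COLS[3:]].to_numpy(dtype=float),
        repetition_time=repetition_time,
    )


def write_table(path, df: pd.DataFrame) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_matrix(path, z_values: np.ndarray, region_ids: np.ndarray, meta: dict | None = None) -> Path:
    """Association matrix as TSV with region ids as header, plus JSON metadata."""
    path = Path(path)
    df = pd.DataFrame(z_values, columns=[str(int(r)) for r in region_ids])
    df.to_csv(path, sep="\t", index=False)
    if meta is not None:
        write_json(path.as_posix() + ".meta.json", meta)
    return path


def read_matrix(path) -> tuple[np.ndarray, np.ndarray, dict | None]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = np.array([int(c) for c in df.columns])
    meta_path = Path(path.as_posix() + ".meta.json")
    meta = read_json(meta_path) if meta_path.exists() else None
    return df.to_numpy(dtype=float), ids, meta


def write_json(path, obj) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_ground_truth(path, gt: GroundTruth) -> Path:
    return write_json(path, gt.to_dict())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(read_json(path))
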