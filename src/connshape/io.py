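"""Reading and writing the pipeline's on-disk formats.

Volumes travel as NIfTI-1 (via nibabel, affine = diag(voxel size)); subject
stacks as 4D NIfTI; covariates as TSV with a mandatory ``subject_id`` column;
network stacks as NPZ; matrices as TSV with region-id headers; parcellation
metadata as JSON next to an integer label NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import Parcellation
from .statmaps import EpicentreSet
from .volume import VolumeGrid

__all__ = [
    "save_volume", "load_volume", "save_stack", "load_stack",
    "save_parcellation", "load_parcellation",
    "save_matrix_tsv", "load_matrix_tsv",
    "save_epicentres", "load_epicentres",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(grid.data, _affine(grid.voxel_size_mm)), str(path))


def load_volume(path, mask: np.ndarray | None = None) -> VolumeGrid:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(float)
    return VolumeGrid(data, voxel_size, mask)


def save_stack(stack: np.ndarray, voxel_size_mm, path) -> None:
    """Save a (n_subjects, nx, ny, nz) stack as a 4D NIfTI."""
    arr = np.moveaxis(np.asarray(stack), 0, -1)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size_mm)), str(path))


def load_stack(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D stack")
    return np.moveaxis(data, -1, 0), voxel_size


def save_parcellation(parc: Parcellation, label_path, meta_path) -> None:
    if parc.label_volume is not None:
        save_volume(parc.label_volume, label_path)
    meta = {
        "region_ids": parc.region_ids.tolist(),
        "hemisphere": {str(k): v for k, v in parc.hemisphere.items()},
        "homotopic": {str(k): int(v) for k, v in parc.homotopic.items()},
        "basal_nuclei": {str(k): bool(v) for k, v in parc.basal_nuclei.items()},
        "volume_mm3": {str(k): float(v) for k, v in parc.volume_mm3.items()},
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_parcellation(label_path, meta_path) -> Parcellation:
    meta = json.loads(Path(meta_path).read_text())
    label = load_volume(label_path) if Path(label_path).exists() else None
    return Parcellation(
        region_ids=np.asarray(meta["region_ids"], dtype=int),
        hemisphere={int(k): v for k, v in meta["hemisphere"].items()},
        homotopic={int(k): int(v) for k, v in meta["homotopic"].items()},
        basal_nuclei={int(k): bool(v) for k, v in meta["basal_nuclei"].items()},
        volume_mm3={int(k): float(v) for k, v in meta["volume_mm3"].items()},
        label_volume=label,
    )


def save_matrix_tsv(matrix: np.ndarray, region_ids, path) -> None:
    ids = [int(i) for i in region_ids]
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="region_id"
    )


def load_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col="region_id")
    ids = frame.index.to_numpy(dtype=int)
    return frame.to_numpy(dtype=float), ids


def save_epicentres(es: EpicentreSet, path) -> None:
    payload = {
        "biomarker_tag": es.biomarker_tag,
        "region_ids": sorted(int(r) for r in es.region_ids),
        "peak_stats": {str(k): float(v) for k, v in es.peak_stats.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_epicentres(path) -> EpicentreSet:
    d = json.loads(Path(path).read_text())
    return EpicentreSet(
        region_ids=set(int(r) for r in d["region_ids"]),
        peak_stats={int(k): float(v) for k, v in d["peak_stats"].items()},
        biomarker_tag=d.get("biomarker_tag", ""),
    )
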