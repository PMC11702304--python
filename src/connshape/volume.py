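"""Voxel-grid container shared by the statistical-map routines.

A :class:`VolumeGrid` bundles a 3D scalar array with its voxel size and an
analysis mask.  It deliberately knows nothing about affines or orientation:
all inputs are assumed to live on one common (already normalised) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeGrid:
    """A 3D scalar volume with voxel dimensions and an in-analysis mask.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (float).
    voxel_size_mm : tuple of 3 positive floats
        Physical voxel dimensions in millimetres.
    mask : ndarray of bool, same shape as ``data``, optional
        Voxels participating in the analysis.  Defaults to all-true.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_mm must be 3 positive values, got {vs}")
        self.voxel_size_mm = vs
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def copy_with(self, data: np.ndarray, mask: np.ndarray | None = None) -> "VolumeGrid":
        return VolumeGrid(
            data=np.asarray(data, dtype=float),
            voxel_size_mm=self.voxel_size_mm,
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
        )


def stack_data(volumes: list[VolumeGrid] | np.ndarray) -> tuple[np.ndarray, VolumeGrid]:
    """Stack per-subject volumes into a (n_subjects, nx, ny, nz) array.

    Accepts either a list of :class:`VolumeGrid` sharing one grid, or a 4D
    ndarray (in which case a default grid is constructed).  Returns the data
    stack and a template grid whose mask is the intersection of the subject
    masks.
    """
    if isinstance(volumes, np.ndarray):
        arr = np.asarray(volumes, dtype=float)
        if arr.ndim != 4:
            raise ValueError("ndarray stack must be 4D (subjects first)")
        template = VolumeGrid(arr[0])
        return arr, template
    if len(volumes) == 0:
        raise ValueError("empty volume stack")
    ref = volumes[0]
    mask = np.ones(ref.shape, dtype=bool)
    data = np.empty((len(volumes),) + ref.shape, dtype=float)
    for i, v in enumerate(volumes):
        if v.shape != ref.shape:
            raise ValueError("all volumes in a stack must share one grid shape")
        if v.voxel_size_mm != ref.voxel_size_mm:
            raise ValueError("all volumes in a stack must share one voxel size")
        data[i] = v.data
        mask &= v.mask
    template = VolumeGrid(ref.data, ref.voxel_size_mm, mask)
    return data, template
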