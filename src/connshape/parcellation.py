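"""Bilateral brain parcellation with homotopic pairing and region retention.

Regions are identified by positive integer labels.  Every region belongs to
one hemisphere and has a homotopic (mirror) partner in the other hemisphere;
the homotopic map is an involution.  A subset of regions can be flagged as
basal nuclei — these are excluded both from epicentre proxies and from the
retained analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VolumeGrid


@dataclass
class Parcellation:
    """Atlas-like parcellation: region identities, hemispheres, homotopic pairs.

    Parameters
    ----------
    region_ids : ndarray of int
        Ordered region labels (positive, unique).
    hemisphere : dict[int, str]
        Map id -> 'L' or 'R'.
    homotopic : dict[int, int]
        Involutive map id -> contralateral partner id (L <-> R).
    basal_nuclei : dict[int, bool]
        Basal-nuclei flag per id.
    volume_mm3 : dict[int, float]
        Region volume, strictly positive.
    label_volume : VolumeGrid, optional
        Integer label image sharing the analysis grid (0 = unlabeled).
    """

    region_ids: np.ndarray
    hemisphere: dict[int, str]
    homotopic: dict[int, int]
    basal_nuclei: dict[int, bool]
    volume_mm3: dict[int, float]
    label_volume: VolumeGrid | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        ids = set(self.region_ids.tolist())
        if len(ids) != len(self.region_ids):
            raise ValueError("region ids must be unique")
        for i in ids:
            j = self.homotopic[i]
            if self.homotopic.get(j) != i:
                raise ValueError(f"homotopic map is not involutive at region {i}")
            if i != j and self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(f"homotopic pair ({i}, {j}) lies in one hemisphere")
            if self.volume_mm3[i] <= 0:
                raise ValueError(f"region {i} has non-positive volume")

    def __len__(self) -> int:
        return len(self.region_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: int) -> int:
        idx = np.nonzero(self.region_ids == region_id)[0]
        if idx.size == 0:
            raise KeyError(f"region {region_id} not in parcellation")
        return int(idx[0])

    def subset(self, keep_ids) -> "Parcellation":
        """Return the parcellation restricted to ``keep_ids`` (order preserved)."""
        keep = set(int(i) for i in keep_ids)
        ids = np.array([i for i in self.region_ids if int(i) in keep], dtype=int)
        return Parcellation(
            region_ids=ids,
            hemisphere={i: self.hemisphere[i] for i in ids},
            homotopic={i: self.homotopic[i] for i in ids},
            basal_nuclei={i: self.basal_nuclei[i] for i in ids},
            volume_mm3={i: self.volume_mm3[i] for i in ids},
            label_volume=self.label_volume,
        )

    def volumes_array(self) -> np.ndarray:
        return np.array([self.volume_mm3[int(i)] for i in self.region_ids], dtype=float)

    def hemisphere_array(self) -> np.ndarray:
        return np.array([self.hemisphere[int(i)] for i in self.region_ids])


@dataclass
class RegionalVector:
    """One scalar per region of a parcellation (metric values, T-scores, ...)."""

    values: np.ndarray
    name: str
    parcellation: Parcellation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.parcellation.n_regions,):
            raise ValueError(
                f"values length {self.values.shape} does not match "
                f"{self.parcellation.n_regions} regions"
            )

    def as_dict(self) -> dict[int, float]:
        return {
            int(i): float(v)
            for i, v in zip(self.parcellation.region_ids, self.values)
        }
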