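"""Shared fixtures: small parcellations, networks and cohorts built in memory."""

import numpy as np
import pytest

from connshape.parcellation import Parcellation
from connshape.synthetic import make_networks, make_parcellation
from connshape.volume import VolumeGrid


@pytest.fixture(scope="session")
def tiny_parcellation() -> Parcellation:
    """12-region bilateral parcellation on a 12^3 grid (1 basal pair)."""
    return make_parcellation(
        n_regions_per_hemisphere=6, grid_shape=(12, 12, 12), n_basal=1, seed=0
    )


@pytest.fixture(scope="session")
def tiny_networks(tiny_parcellation):
    return make_networks(
        tiny_parcellation, n_hubs=2, module_count=2, subject_n=12, seed=1
    )


@pytest.fixture(scope="session")
def desk_parcellation() -> Parcellation:
    """Default-scale parcellation (60 regions, 40x48x40 grid)."""
    return make_parcellation(seed=11)


@pytest.fixture(scope="session")
def desk_networks(desk_parcellation):
    return make_networks(desk_parcellation, seed=12)


def manual_parcellation(labels: np.ndarray, basal=(), voxel_size=(1.5, 1.5, 1.5)):
    """Hand-built parcellation from an even number of labels 1..2n (L then R)."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n = len(ids) // 2
    voxel_volume = float(np.prod(voxel_size))
    counts = {int(i): int((labels == i).sum()) for i in ids}
    return Parcellation(
        region_ids=ids.astype(int),
        hemisphere={int(i): ("L" if i <= n else "R") for i in ids},
        homotopic={int(i): int(i + n if i <= n else i - n) for i in ids},
        basal_nuclei={int(i): int(i) in set(basal) for i in ids},
        volume_mm3={int(i): max(counts[int(i)], 1) * voxel_volume for i in ids},
        label_volume=VolumeGrid(labels.astype(float), voxel_size),
    )
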