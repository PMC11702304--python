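"""Group connectome construction and graph metrics for spreading mechanisms.

Three region-by-region networks feed the predictor matrix:

* a **structural** connectome — a backbone of edges whose presence across
  subjects beats chance under an exact sign test (BH-FDR corrected), weighted
  by mean streamline count normalised by the mean volume of the two regions;
* a **functional** connectome — the group-mean correlation matrix with
  non-significant edges (one-tailed t on Fisher-z values, BH-FDR) zeroed;
* a **cortical-distance** network — a metric distance matrix whose hemispheres
  are disconnected by construction.

From each network three mechanism features are extracted per region: nodal
strength (hubness / nodal stress), the Laplacian diffusion mode (slowest
spatial pattern of network diffusion), and — per biomarker — topological
proximity to the epicentre proxies.  The distance network contributes the
analogous confound features, with strength and diffusion computed on
inverted distances and the epicentre feature kept as a raw path length.
The nine standardized columns form the :class:`PredictorMatrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .parcellation import Parcellation, RegionalVector
from .statmaps import EpicentreSet

__all__ = [
    "WeightedGraph",
    "PredictorMatrix",
    "PREDICTOR_COLUMNS",
    "CONFOUND_COLUMNS",
    "retain_regions",
    "structural_group_network",
    "shrinkage_correlation",
    "functional_group_network",
    "nodal_strength",
    "diffusion_mode",
    "distance_to_affinity",
    "topological_proximity",
    "cortical_path_length",
    "assemble_predictors",
]

#: Fixed order of the nine regressors.
PREDICTOR_COLUMNS = [
    "structural_nodal_strength",
    "structural_diffusion_mode",
    "functional_nodal_strength",
    "functional_diffusion_mode",
    "cortical_distance_nodal_strength",
    "cortical_distance_diffusion_mode",
    "structural_proximity_to_epicentres",
    "functional_proximity_to_epicentres",
    "cortical_distance_path_length",
]

#: The three cortical-distance-derived columns act as confounds.
CONFOUND_COLUMNS = [c for c in PREDICTOR_COLUMNS if c.startswith("cortical_distance")]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative region-by-region weight matrix tied to a parcellation."""

    weights: np.ndarray
    parcellation: Parcellation
    kind: str  # "structural" | "functional" | "distance"
    inverted: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.parcellation.n_regions
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.kind not in ("structural", "functional", "distance"):
            raise ValueError(f"unknown graph kind {self.kind!r}")

    @property
    def n_regions(self) -> int:
        return self.parcellation.n_regions


@dataclass
class PredictorMatrix:
    """Regions x 9 standardized regressors with mechanism tags and confound flags."""

    matrix: pd.DataFrame                       # index: region ids, 9 columns
    confound: dict[str, bool]
    parcellation: Parcellation
    biomarker_tag: str = ""
    epicentre_regions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if list(self.matrix.columns) != PREDICTOR_COLUMNS:
            raise ValueError("predictor matrix must have the nine canonical columns")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="region_id")


def retain_regions(
    parcellation: Parcellation,
    min_voxels: int = 100,
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5),
) -> Parcellation:
    """Drop basal nuclei and too-small parcels, plus their homotopic partners.

    A parcel is too small when its volume falls below
    ``min_voxels * voxel volume`` (100 voxels at 1.5 mm isotropic =
    337.5 mm^3).  Whenever a parcel is dropped its contralateral partner is
    dropped too, keeping the retained set closed under homotopy.
    """
    min_volume = min_voxels * float(np.prod(voxel_size_mm))
    dropped = set()
    for rid in parcellation.region_ids:
        rid = int(rid)
        if parcellation.basal_nuclei.get(rid, False):
            dropped.add(rid)
        elif parcellation.volume_mm3[rid] < min_volume:
            dropped.add(rid)
    for rid in list(dropped):
        dropped.add(int(parcellation.homotopic[rid]))
    keep = [int(i) for i in parcellation.region_ids if int(i) not in dropped]
    return parcellation.subset(keep)


def _fdr_mask(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg rejection mask."""
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def _symmetrize(mat: np.ndarray, label: str) -> np.ndarray:
    if not np.allclose(mat, mat.T):
        warnings.warn(f"asymmetric {label} matrix symmetrized by averaging")
        mat = (mat + mat.T) / 2.0
    return mat


def structural_group_network(
    count_stack,
    parcellation: Parcellation,
    fdr_q: float = 0.05,
) -> WeightedGraph:
    """Backbone structural connectome from per-subject streamline counts.

    Each edge's presence (count > 0) across subjects is tested against chance
    with an exact one-sided binomial sign test (presence probability 0.5);
    BH-FDR at ``fdr_q`` over all edges defines the binary backbone.  Surviving
    edges are weighted by the mean over subjects of count divided by the mean
    volume of the two regions; all other edges are zero.
    """
    counts = np.asarray(count_stack, dtype=float)
    if counts.ndim != 3 or counts.shape[1] != counts.shape[2]:
        raise ValueError("count_stack must be (n_subjects, n_regions, n_regions)")
    n_sub, n_reg, _ = counts.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects for the sign test")
    if n_reg != parcellation.n_regions:
        raise ValueError("count matrices do not match the parcellation")
    if (counts < 0).any():
        raise ValueError("streamline counts must be nonnegative")
    counts = np.stack([_symmetrize(c, "subject count") for c in counts])

    iu = np.triu_indices(n_reg, k=1)
    present = (counts > 0)[:, iu[0], iu[1]]          # (n_sub, n_edges)
    k = present.sum(axis=0)
    # one-sided exact binomial: P(X >= k) under Binomial(n, 0.5)
    pvals = stats.binom.sf(k - 1, n_sub, 0.5)
    keep = _fdr_mask(pvals, fdr_q)

    vols = parcellation.volumes_array()
    mean_vol = (vols[iu[0]] + vols[iu[1]]) / 2.0
    edge_w = counts[:, iu[0], iu[1]].mean(axis=0) / mean_vol
    edge_w[~keep] = 0.0

    weights = np.zeros((n_reg, n_reg))
    weights[iu] = edge_w
    weights += weights.T
    return WeightedGraph(weights, parcellation, kind="structural")


def shrinkage_correlation(timeseries: np.ndarray) -> np.ndarray:
    """Ledoit–Wolf shrunk covariance of region time series, as a correlation.

    ``timeseries`` is regions x time.  Constant rows are rejected because a
    correlation is undefined for them.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("timeseries must be regions x time with >= 2 time points")
    sd = ts.std(axis=1)
    if (sd == 0).any():
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"constant time series for region indices {bad}")
    cov = LedoitWolf(assume_centered=False).fit(ts.T).covariance_
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def functional_group_network(
    corr_stack,
    parcellation: Parcellation,
    fdr_q: float = 0.05,
) -> WeightedGraph:
    """Group functional connectome masked by a one-tailed t-test on Fisher z.

    Per edge, subject correlations are Fisher z-transformed and tested
    (one-tailed, positive) against zero; BH-FDR at ``fdr_q`` masks the group
    mean correlation matrix.  Edges with zero cross-subject variance count as
    significant when their mean z is positive.  Surviving negative means are
    clipped to 0 (downstream metrics need nonnegative weights).
    """
    corrs = np.asarray(corr_stack, dtype=float)
    if corrs.ndim != 3 or corrs.shape[1] != corrs.shape[2]:
        raise ValueError("corr_stack must be (n_subjects, n_regions, n_regions)")
    n_sub, n_reg, _ = corrs.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    if n_reg != parcellation.n_regions:
        raise ValueError("correlation matrices do not match the parcellation")
    corrs = np.stack([_symmetrize(c, "subject correlation") for c in corrs])

    iu = np.triu_indices(n_reg, k=1)
    r = corrs[:, iu[0], iu[1]]
    if (np.abs(r) >= 1).any():
        raise ValueError("off-diagonal |r| = 1: Fisher z undefined")
    z = np.arctanh(r)
    zm = z.mean(axis=0)
    zs = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = zm / (zs / np.sqrt(n_sub))
    pvals = stats.t.sf(t, n_sub - 1)
    # zero-variance edges: significant iff the common z is positive
    degen = zs == 0
    pvals[degen] = np.where(zm[degen] > 0, 0.0, 1.0)
    keep = _fdr_mask(pvals, fdr_q)

    mean_r = r.mean(axis=0)
    edge_w = np.where(keep, mean_r, 0.0)
    n_neg = int((edge_w < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} surviving negative edge(s) clipped to 0")
        edge_w = np.clip(edge_w, 0.0, None)

    weights = np.zeros((n_reg, n_reg))
    weights[iu] = edge_w
    weights += weights.T
    return WeightedGraph(weights, parcellation, kind="functional")


def nodal_strength(graph: WeightedGraph) -> RegionalVector:
    """Sum of edge weights incident to each region (hubness proxy).

    For the distance network the graph must be inverted to affinities first
    (:func:`distance_to_affinity`): summing raw distances has the opposite
    meaning.
    """
    if graph.kind == "distance" and not graph.inverted:
        raise ValueError(
            "nodal strength on a distance network requires distance_to_affinity first"
        )
    return RegionalVector(
        values=graph.weights.sum(axis=1),
        name=f"{graph.kind}_nodal_strength",
        parcellation=graph.parcellation,
    )


def diffusion_mode(graph: WeightedGraph) -> tuple[RegionalVector, np.ndarray]:
    """Unsigned Fiedler mode of the graph Laplacian, per connected component.

    For each connected component of the weight matrix, the unnormalized
    Laplacian L = D - W is eigendecomposed and the unit-norm eigenvector of
    the smallest strictly positive eigenvalue is taken.  The sign pattern of
    that eigenvector (before the absolute value) partitions the component into
    two weakly communicating clusters, returned as ``cluster_labels`` (0/1 per
    region; -1 for singleton components).  The returned vector holds the
    elementwise absolute value, with per-component modes summed into one
    vector (each is zero outside its component) — for a hemisphere-split
    distance network this realises the sum of the two per-hemisphere modes.
    """
    if graph.kind == "distance" and not graph.inverted:
        raise ValueError(
            "diffusion mode on a distance network requires distance_to_affinity first"
        )
    w = graph.weights
    n = w.shape[0]
    n_comp, comp = connected_components(sparse.csr_matrix(w != 0), directed=False)
    mode = np.zeros(n)
    clusters = np.full(n, -1, dtype=int)
    for c in range(n_comp):
        idx = np.nonzero(comp == c)[0]
        if idx.size == 1:
            warnings.warn(f"singleton component at region index {idx[0]}: mode 0")
            continue
        sub = w[np.ix_(idx, idx)]
        lap = np.diag(sub.sum(axis=1)) - sub
        eigval, eigvec = np.linalg.eigh(lap)
        scale = max(eigval.max(), 1.0)
        positive = np.nonzero(eigval > 1e-10 * scale)[0]
        if positive.size == 0:  # all-zero weights inside the component
            continue
        k = positive[0]
        v = eigvec[:, k]
        clusters[idx] = (v >= 0).astype(int)
        mode[idx] = np.abs(v)
    return (
        RegionalVector(
            values=mode,
            name=f"{graph.kind}_diffusion_mode",
            parcellation=graph.parcellation,
        ),
        clusters,
    )


def distance_to_affinity(distance_graph: WeightedGraph) -> WeightedGraph:
    """Invert nonzero cortical distances into affinities (zeros stay zero)."""
    if distance_graph.kind != "distance":
        raise ValueError("distance_to_affinity expects a distance network")
    w = distance_graph.weights
    out = np.zeros_like(w)
    nz = w != 0
    out[nz] = 1.0 / w[nz]
    return WeightedGraph(
        out,
        distance_graph.parcellation,
        kind="distance",
        inverted=not distance_graph.inverted,
    )


def _epicentre_indices(
    parcellation: Parcellation, epicentres: EpicentreSet
) -> np.ndarray:
    idx = [
        parcellation.index_of(r)
        for r in sorted(epicentres.region_ids)
        if int(r) in set(int(i) for i in parcellation.region_ids)
    ]
    if not idx:
        raise ValueError("no epicentre region intersects the retained parcellation")
    return np.asarray(idx, dtype=int)


def _shortest_paths(lengths: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Dijkstra distances from epicentre rows over a dense length matrix."""
    graph = sparse.csr_matrix(lengths)
    return dijkstra(graph, directed=False, indices=sources)


def _mean_distance_to_epicentres(
    dist: np.ndarray, n_regions: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region mean of finite distances to the epicentres.

    Returns (mean, n_reachable); unreachable epicentres are excluded from the
    mean with a warning.
    """
    finite = np.isfinite(dist)
    n_reach = finite.sum(axis=0)
    if (n_reach < dist.shape[0]).any():
        n_aff = int((n_reach < dist.shape[0]).sum())
        warnings.warn(
            f"{n_aff} region(s) cannot reach every epicentre; unreachable "
            "epicentres excluded from their mean"
        )
    with np.errstate(invalid="ignore"):
        mean = np.where(
            n_reach > 0,
            np.where(finite, dist, 0.0).sum(axis=0) / np.maximum(n_reach, 1),
            np.nan,
        )
    return mean, n_reach


def topological_proximity(
    graph: WeightedGraph, epicentres: EpicentreSet
) -> RegionalVector:
    """Inverse mean shortest-path length from each region to the epicentres.

    Connectivity weights are turned into lengths by inversion (1/w on nonzero
    edges).  A region's distance to itself is 0 and participates in the mean.
    Regions reaching no epicentre get proximity 0.  The degenerate case of a
    region whose mean distance is exactly 0 (a sole epicentre) is capped at
    the maximum finite proximity in the map to keep the vector finite.
    """
    if graph.kind == "distance":
        raise ValueError("topological_proximity expects a connectivity graph")
    w = graph.weights
    lengths = np.zeros_like(w)
    nz = w != 0
    lengths[nz] = 1.0 / w[nz]
    src = _epicentre_indices(graph.parcellation, epicentres)
    dist = _shortest_paths(lengths, src)
    mean, n_reach = _mean_distance_to_epicentres(dist, graph.n_regions)

    prox = np.zeros(graph.n_regions)
    reachable = n_reach > 0
    positive = reachable & (mean > 0)
    prox[positive] = 1.0 / mean[positive]
    degenerate = reachable & (mean == 0)
    if degenerate.any():
        cap = prox[positive].max() if positive.any() else 1.0
        prox[degenerate] = cap
    return RegionalVector(
        values=prox,
        name=f"{graph.kind}_proximity_to_epicentres",
        parcellation=graph.parcellation,
    )


def cortical_path_length(
    distance_graph: WeightedGraph, epicentres: EpicentreSet
) -> RegionalVector:
    """Mean shortest cortical path length from each region to the epicentres.

    Operates on the raw (non-inverted) distance network; larger means farther
    (this confound is a path length, not a proximity).  Cross-hemisphere
    unreachable pairs are excluded from the mean; a region reaching no
    epicentre gets the maximum finite mean length in the map (the farthest
    plausible value, keeping the vector finite).
    """
    if distance_graph.kind != "distance" or distance_graph.inverted:
        raise ValueError("cortical_path_length expects a raw distance network")
    src = _epicentre_indices(distance_graph.parcellation, epicentres)
    dist = _shortest_paths(distance_graph.weights, src)
    mean, n_reach = _mean_distance_to_epicentres(dist, distance_graph.n_regions)
    out = mean.copy()
    unreachable = n_reach == 0
    if unreachable.any():
        finite = out[~unreachable]
        out[unreachable] = finite.max() if finite.size else 0.0
    return RegionalVector(
        values=out,
        name="cortical_distance_path_length",
        parcellation=distance_graph.parcellation,
    )


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Rescale columns to mean 0, SD 1 (population SD, ddof 0)."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = np.nonzero(sd == 0)[0].tolist()
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (x - mean) / sd


def assemble_predictors(
    struct: WeightedGraph,
    func: WeightedGraph,
    dist: WeightedGraph,
    epicentres: EpicentreSet,
    biomarker_tag: str = "",
) -> PredictorMatrix:
    """Build the nine-regressor standardized predictor matrix.

    Column order is fixed (:data:`PREDICTOR_COLUMNS`): structural and
    functional strength and diffusion, the distance-network confound analogues
    (strength and diffusion on inverted distances), the two biomarker-specific
    topological proximities, and the cortical path-length confound.  Each
    column is rescaled to mean 0, SD 1.
    """
    parc = struct.parcellation
    for g in (func, dist):
        if g.parcellation.n_regions != parc.n_regions or not np.array_equal(
            g.parcellation.region_ids, parc.region_ids
        ):
            raise ValueError("all graphs must share one retained parcellation")
    if dist.inverted:
        raise ValueError("pass the raw (non-inverted) distance network")
    affinity = distance_to_affinity(dist)

    cols = {
        "structural_nodal_strength": nodal_strength(struct).values,
        "structural_diffusion_mode": diffusion_mode(struct)[0].values,
        "functional_nodal_strength": nodal_strength(func).values,
        "functional_diffusion_mode": diffusion_mode(func)[0].values,
        "cortical_distance_nodal_strength": nodal_strength(affinity).values,
        "cortical_distance_diffusion_mode": diffusion_mode(affinity)[0].values,
        "structural_proximity_to_epicentres": topological_proximity(
            struct, epicentres
        ).values,
        "functional_proximity_to_epicentres": topological_proximity(
            func, epicentres
        ).values,
        "cortical_distance_path_length": cortical_path_length(
            dist, epicentres
        ).values,
    }
    raw = np.column_stack([cols[c] for c in PREDICTOR_COLUMNS])
    standardized = standardize_columns(raw)
    frame = pd.DataFrame(
        standardized, index=parc.region_ids.astype(int), columns=PREDICTOR_COLUMNS
    )
    return PredictorMatrix(
        matrix=frame,
        confound={c: c in CONFOUND_COLUMNS for c in PREDICTOR_COLUMNS},
        parcellation=parc,
        biomarker_tag=biomarker_tag,
        epicentre_regions=set(int(r) for r in epicentres.region_ids),
    )
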