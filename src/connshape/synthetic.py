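"""Synthetic study generator: parcellation, connectomes, cohorts, ground truth.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes, plus the generating parameters needed for
parameter-recovery tests:

* :func:`make_parcellation` — a bilateral voxel parcellation with exact
  homotopic mirror pairs and basal-nuclei flags;
* :func:`make_networks` — hub-structured structural count stacks (Poisson
  subject noise), modular positive-definite functional correlation stacks,
  and a metric cortical-distance matrix whose hemispheres are disconnected;
* :func:`make_cohort` — control/patient voxel stacks whose regional pattern
  is a known linear mixture of the nine network predictors plus Gaussian
  noise, painted onto parcel voxels with voxel noise and covariate effects;
* :func:`make_regional_cohort` — the same generative model at the regional
  level (subjects x regions), skipping voxel painting, for large repeated
  simulation studies;
* :func:`analytic_lmg_oracle` — the exact population LMG decomposition from
  a covariance matrix, the ground truth recovery targets are measured
  against.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .networks import (
    PredictorMatrix,
    WeightedGraph,
    assemble_predictors,
    functional_group_network,
    retain_regions,
    structural_group_network,
)
from .parcellation import Parcellation
from .statmaps import EpicentreSet
from .volume import VolumeGrid

__all__ = [
    "SyntheticTruth",
    "SyntheticNetworks",
    "make_parcellation",
    "make_networks",
    "make_cohort",
    "make_regional_cohort",
    "analytic_lmg_oracle",
    "default_truth_spec",
]


@dataclass
class SyntheticTruth:
    """Generating parameters and analytic recovery targets of a cohort."""

    beta: np.ndarray                    # 9-vector of generating weights
    noise_sd: float                     # region-level pattern noise SD
    analytic_lmg: np.ndarray            # population LMG decomposition
    epicentre_regions: set[int]
    covariate_effects: dict[str, float]
    population_r2: float = 0.0
    regional_pattern: np.ndarray = field(default=None, repr=False)
    predictors: PredictorMatrix = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.analytic_lmg is not None:
            s = self.analytic_lmg.sum()
            if (self.analytic_lmg < -1e-10).any():
                raise ValueError("analytic LMG entries must be nonnegative")
            if self.population_r2 and abs(s - self.population_r2) > 1e-8:
                raise ValueError("analytic LMG must sum to the population R²")

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "beta": self.beta.tolist(),
            "noise_sd": self.noise_sd,
            "analytic_lmg": self.analytic_lmg.tolist(),
            "epicentre_regions": sorted(int(r) for r in self.epicentre_regions),
            "covariate_effects": self.covariate_effects,
            "population_r2": self.population_r2,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class SyntheticNetworks:
    """Subject-level network stacks plus the group distance matrix."""

    struct_counts: np.ndarray           # (n_subjects, n, n) streamline counts
    func_corr: np.ndarray               # (n_subjects, n, n) correlations
    distance: np.ndarray                # (n, n); 0 across hemispheres
    centroids_mm: np.ndarray            # (n, 3)
    hub_regions: set[int]


# ---------------------------------------------------------------------------
# parcellation


def make_parcellation(
    n_regions_per_hemisphere: int = 30,
    grid_shape: tuple[int, int, int] = (40, 48, 40),
    n_basal: int = 2,
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5),
) -> Parcellation:
    """Mirrored bilateral parcellation on a voxel grid.

    The left half of the grid (lower x) is partitioned into
    ``n_regions_per_hemisphere`` compact Voronoi parcels around jittered
    quasi-grid seeds; the right hemisphere is the exact voxel mirror, so
    homotopic volumes match.  The ``n_basal`` parcels per hemisphere closest
    to the grid centre are flagged as basal nuclei.  Left regions get ids
    1..n, right ids n+1..2n, with ``i <-> i+n`` homotopic pairs.
    """
    nx, ny, nz = grid_shape
    n = n_regions_per_hemisphere
    half = nx // 2
    if half * ny * nz < 8 * n:
        raise ValueError("grid too small for the requested number of parcels")
    rng = np.random.default_rng(seed)

    # quasi-grid of parcel seeds in the left half, with jitter
    k = max(1, int(math.ceil(n ** (1 / 3))))
    axes = [
        np.linspace(1, half - 2, k),
        np.linspace(1, ny - 2, k),
        np.linspace(1, nz - 2, k),
    ]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    seeds = mesh[rng.permutation(len(mesh))[:n]]
    seeds += rng.uniform(-0.5, 0.5, seeds.shape)

    ix, iy, iz = np.meshgrid(
        np.arange(half), np.arange(ny), np.arange(nz), indexing="ij"
    )
    coords = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3).astype(float)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    left_labels = d2.argmin(axis=1).reshape(half, ny, nz) + 1

    labels = np.zeros(grid_shape, dtype=int)
    labels[:half] = left_labels
    labels[nx - half:] = left_labels[::-1] + n  # exact mirror in x

    region_ids = np.arange(1, 2 * n + 1)
    hemisphere = {int(i): ("L" if i <= n else "R") for i in region_ids}
    homotopic = {int(i): int(i + n if i <= n else i - n) for i in region_ids}

    centre = np.array([half - 0.5, (ny - 1) / 2, (nz - 1) / 2])
    seed_dist = np.linalg.norm(seeds - centre, axis=1)
    basal_left = set((np.argsort(seed_dist)[:n_basal] + 1).tolist())
    basal = {
        int(i): (i in basal_left or (i - n) in basal_left) for i in region_ids
    }

    voxel_volume = float(np.prod(voxel_size_mm))
    counts = np.bincount(labels.ravel(), minlength=2 * n + 1)
    volume = {int(i): counts[i] * voxel_volume for i in region_ids}

    return Parcellation(
        region_ids=region_ids,
        hemisphere=hemisphere,
        homotopic=homotopic,
        basal_nuclei=basal,
        volume_mm3=volume,
        label_volume=VolumeGrid(labels.astype(float), voxel_size_mm),
    )


def region_centroids_mm(parcellation: Parcellation) -> np.ndarray:
    """Parcel centroids in millimetres from the label volume."""
    labels = parcellation.label_volume.data.astype(int)
    vs = np.asarray(parcellation.label_volume.voxel_size_mm)
    out = np.empty((parcellation.n_regions, 3))
    for k, rid in enumerate(parcellation.region_ids):
        vox = np.argwhere(labels == int(rid))
        out[k] = vox.mean(axis=0) * vs
    return out


# ---------------------------------------------------------------------------
# networks


def make_networks(
    parcellation: Parcellation,
    n_hubs: int = 3,
    module_count: int = 4,
    subject_n: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticNetworks:
    """Hub-structured connectome stacks and a metric distance matrix.

    Structural base weights follow a multiplicative gain model (lognormal
    nodal gains, boosted for ``n_hubs`` homotopic hub pairs) modulated by
    module co-membership, spatial decay and strong homotopic edges; subject
    matrices are Poisson draws around the base scaled by a per-subject
    lognormal gain.  Functional matrices come from a per-subject noisy
    module-factor model, hence are symmetric positive definite.  Distances
    are within-hemisphere shortest-path lengths along a neighbour graph of
    parcel centroids (metric by construction); hemispheres stay disconnected.
    """
    rng = np.random.default_rng(seed)
    n = parcellation.n_regions
    half = n // 2
    cent = region_centroids_mm(parcellation)
    hemi = parcellation.hemisphere_array()

    # nodal gains with homotopic symmetry; hubs boosted
    gains_left = rng.lognormal(mean=0.0, sigma=0.4, size=half)
    non_basal_left = [
        i for i in range(half)
        if not parcellation.basal_nuclei[int(parcellation.region_ids[i])]
    ]
    hub_left = rng.choice(non_basal_left, size=min(n_hubs, len(non_basal_left)),
                          replace=False)
    gains_left[hub_left] = 5.0  # hubs dominate the gain distribution
    gains = np.concatenate([gains_left, gains_left])
    hub_regions = {
        int(parcellation.region_ids[i]) for i in hub_left
    } | {
        int(parcellation.homotopic[int(parcellation.region_ids[i])])
        for i in hub_left
    }

    modules = _module_assignment(parcellation, cent, module_count)
    d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
    decay = np.exp(-d / (0.5 * d.max() + 1e-12))
    same_module = (modules[:, None] == modules[None, :]).astype(float)
    base = np.outer(gains, gains) * (0.15 + 0.85 * same_module) * decay
    homotopic_idx = np.array(
        [parcellation.index_of(parcellation.homotopic[int(r)])
         for r in parcellation.region_ids]
    )
    base[np.arange(n), homotopic_idx] += 1.5 * gains
    base = (base + base.T) / 2.0
    np.fill_diagonal(base, 0.0)
    # sparsify the weakest tail to a realistic density, then put the kept
    # edges on a streamline-count scale where presence is reliable per subject
    thr = np.quantile(base[np.triu_indices(n, 1)], 0.35)
    base[base < thr] = 0.0
    base *= 5.0 / thr

    struct = np.empty((subject_n, n, n))
    iu = np.triu_indices(n, 1)
    for s in range(subject_n):
        gain_s = rng.lognormal(mean=0.0, sigma=0.2)
        lam = base[iu] * gain_s
        draw = rng.poisson(lam)
        mat = np.zeros((n, n))
        mat[iu] = draw
        struct[s] = mat + mat.T

    # functional: module factor model, SPD per subject
    loadings = 0.2 * rng.standard_normal((n, module_count))
    loadings[np.arange(n), modules] += 0.8
    func = np.empty((subject_n, n, n))
    for s in range(subject_n):
        lam_s = loadings + noise_sd * rng.standard_normal(loadings.shape)
        cov = lam_s @ lam_s.T + np.diag(0.5 + 0.1 * rng.random(n))
        dd = np.sqrt(np.diag(cov))
        corr = cov / np.outer(dd, dd)
        np.fill_diagonal(corr, 1.0)
        func[s] = (corr + corr.T) / 2.0

    distance = _hemisphere_distances(cent, hemi)
    return SyntheticNetworks(
        struct_counts=struct,
        func_corr=func,
        distance=distance,
        centroids_mm=cent,
        hub_regions=hub_regions,
    )


def _module_assignment(
    parcellation: Parcellation, cent: np.ndarray, module_count: int
) -> np.ndarray:
    """Mirror-symmetric module labels from posterior-anterior position."""
    n = parcellation.n_regions
    modules = np.empty(n, dtype=int)
    for hemi_label in ("L", "R"):
        idx = np.nonzero(parcellation.hemisphere_array() == hemi_label)[0]
        order = np.argsort(cent[idx, 1], kind="stable")
        bins = np.array_split(order, module_count)
        for mod, members in enumerate(bins):
            modules[idx[members]] = mod
    return modules


def _hemisphere_distances(cent: np.ndarray, hemi: np.ndarray) -> np.ndarray:
    """Within-hemisphere shortest-path distances on a centroid neighbour graph."""
    n = len(cent)
    out = np.zeros((n, n))
    for side in ("L", "R"):
        idx = np.nonzero(hemi == side)[0]
        pts = cent[idx]
        k = len(idx)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        adj = np.zeros_like(d)
        n_neigh = min(6, k - 1)
        for i in range(k):
            order = np.argsort(d[i])
            for j in order[1:n_neigh + 1]:
                adj[i, j] = adj[j, i] = d[i, j]
        # chain along the anterior-posterior axis guarantees connectivity
        chain = np.argsort(pts[:, 1], kind="stable")
        for a, b in zip(chain[:-1], chain[1:]):
            adj[a, b] = adj[b, a] = d[a, b]
        sp = dijkstra(sparse.csr_matrix(adj), directed=False)
        out[np.ix_(idx, idx)] = sp
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# cohorts


def default_truth_spec(dominant: str = "structural_proximity_to_epicentres"):
    """Default generating weights: one dominant mechanism, population R² = 0.5."""
    from .networks import PREDICTOR_COLUMNS

    beta = np.zeros(9)
    beta[PREDICTOR_COLUMNS.index(dominant)] = 1.0
    return {
        "beta": beta,
        "noise_sd": 1.0,
        "covariate_effects": {"age": 0.02, "education": -0.05},
        "subject_noise_sd": 1.0,
        "voxel_noise_sd": 1.0,
        "pattern_scale": 2.0,
    }


def _prepare_truth(
    parcellation: Parcellation,
    networks: SyntheticNetworks,
    truth_spec: dict,
    rng: np.random.Generator,
) -> tuple[Parcellation, PredictorMatrix, SyntheticTruth]:
    """Retained parcellation, predictor matrix and truth from a truth-spec dict."""
    beta = np.asarray(truth_spec["beta"], dtype=float)
    if beta.shape != (9,):
        raise ValueError("truth beta must have length 9")
    noise_sd = float(truth_spec["noise_sd"])

    retained = retain_regions(parcellation)
    ridx = np.array([parcellation.index_of(int(r)) for r in retained.region_ids])
    struct = structural_group_network(
        networks.struct_counts[np.ix_(np.arange(len(networks.struct_counts)),
                                      ridx, ridx)],
        retained,
    )
    func = functional_group_network(
        networks.func_corr[np.ix_(np.arange(len(networks.func_corr)),
                                  ridx, ridx)],
        retained,
    )
    dist = WeightedGraph(
        networks.distance[np.ix_(ridx, ridx)], retained, kind="distance"
    )

    epi = truth_spec.get("epicentre_regions")
    if epi is None:
        retained_hubs = [r for r in sorted(networks.hub_regions)
                         if r in set(int(i) for i in retained.region_ids)]
        if not retained_hubs:
            raise ValueError("no hub region survives retention; pass epicentres")
        first = retained_hubs[0]
        epi = {first, int(retained.homotopic[first])}
    epi = set(int(r) for r in epi)
    epicentres = EpicentreSet(
        region_ids=epi, peak_stats={r: 1.0 for r in epi}, biomarker_tag="synthetic"
    )
    X = assemble_predictors(struct, func, dist, epicentres, biomarker_tag="synthetic")

    pattern = X.values @ beta + rng.normal(0.0, noise_sd, size=retained.n_regions)
    sigma_xx = X.values.T @ X.values / retained.n_regions
    cov = np.empty((10, 10))
    cov[:9, :9] = sigma_xx
    cov[:9, 9] = cov[9, :9] = sigma_xx @ beta
    cov[9, 9] = beta @ sigma_xx @ beta + noise_sd**2
    analytic = analytic_lmg_oracle(cov)
    pop_r2 = float((beta @ sigma_xx @ beta) / cov[9, 9])

    truth = SyntheticTruth(
        beta=beta,
        noise_sd=noise_sd,
        analytic_lmg=analytic,
        epicentre_regions=epi,
        covariate_effects=dict(truth_spec.get("covariate_effects", {})),
        population_r2=pop_r2,
        regional_pattern=pattern,
        predictors=X,
    )
    return retained, X, truth


def make_regional_cohort(
    parcellation: Parcellation,
    networks: SyntheticNetworks,
    truth_spec: dict | None = None,
    n_patients: int = 40,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[np.ndarray, PredictorMatrix, SyntheticTruth]:
    """Patient regional scores (subjects x retained regions) plus ground truth.

    Each patient's regional vector is the shared pattern ``X beta + pattern
    noise`` plus independent subject noise — the regional-level view of
    :func:`make_cohort`, suitable for repeated simulation studies.

    Passing an existing ``truth`` reuses its realized regional pattern and
    predictors: the pattern is the *population* topography, so two cohorts
    sampled from the same generative mixture share it and differ only in
    their subject draws.
    """
    if truth_spec is None:
        truth_spec = default_truth_spec()
    rng = np.random.default_rng(seed)
    if truth is None:
        retained_n = None
        _, X, truth = _prepare_truth(parcellation, networks, truth_spec, rng)
    else:
        X = truth.predictors
        if X is None or truth.regional_pattern is None:
            raise ValueError("reused truth must carry predictors and pattern")
    subject_noise = float(truth_spec.get("subject_noise_sd", 1.0))
    n_regions = truth.regional_pattern.shape[0]
    scores = truth.regional_pattern[None, :] + rng.normal(
        0.0, subject_noise, size=(n_patients, n_regions)
    )
    return scores, X, truth


def make_cohort(
    parcellation: Parcellation,
    networks: SyntheticNetworks,
    truth_spec: dict | None = None,
    n_controls: int = 20,
    n_patients: int = 40,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, SyntheticTruth]:
    """Voxel-level control and patient stacks embedding a known mixture pattern.

    Controls carry covariate effects (age, education) plus voxel noise;
    patients additionally carry the regional pattern ``X beta + noise``
    (scaled by ``pattern_scale`` to control lesion amplitude in W-score
    units), with per-subject regional noise, painted uniformly over each
    parcel's voxels.  Returns (control stack, patient stack, covariate table,
    truth); the covariate table carries group, stage, age and education per
    subject.
    """
    if truth_spec is None:
        truth_spec = default_truth_spec()
    rng = np.random.default_rng(seed)
    retained, X, truth = _prepare_truth(parcellation, networks, truth_spec, rng)

    labels = parcellation.label_volume.data.astype(int)
    shape = labels.shape
    voxel_noise = float(truth_spec.get("voxel_noise_sd", 1.0))
    subject_noise = float(truth_spec.get("subject_noise_sd", 1.0))
    scale = float(truth_spec.get("pattern_scale", 2.0))
    eff = truth.covariate_effects

    n_total = n_controls + n_patients
    age = rng.uniform(55, 90, size=n_total)
    edu = rng.uniform(8, 20, size=n_total)
    group = np.array(["control"] * n_controls + ["patient"] * n_patients)
    stages = np.array(
        ["NA"] * n_controls
        + [("EMCI", "LMCI", "AD")[i % 3] for i in range(n_patients)]
    )
    covariates = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n_total)],
            "group": group,
            "stage": stages,
            "age": age,
            "education": edu,
        }
    )

    region_voxels = {
        int(r): labels == int(r) for r in retained.region_ids
    }
    controls = np.empty((n_controls,) + shape)
    patients = np.empty((n_patients,) + shape)
    for i in range(n_controls):
        base = eff.get("age", 0.0) * age[i] + eff.get("education", 0.0) * edu[i]
        controls[i] = base + rng.normal(0.0, voxel_noise, size=shape)
    for i in range(n_patients):
        k = n_controls + i
        base = eff.get("age", 0.0) * age[k] + eff.get("education", 0.0) * edu[k]
        vol = base + rng.normal(0.0, voxel_noise, size=shape)
        regional = truth.regional_pattern + rng.normal(
            0.0, subject_noise, size=retained.n_regions
        )
        for j, r in enumerate(retained.region_ids):
            vol[region_voxels[int(r)]] += scale * regional[j]
        patients[i] = vol
    return controls, patients, covariates, truth


# ---------------------------------------------------------------------------
# population oracle


def analytic_lmg_oracle(cov: np.ndarray) -> np.ndarray:
    """Exact population LMG from the covariance of (X_1..X_m, y).

    For each subset S, the population subset R² is
    ``sigma_yS Sigma_S^{-1} sigma_Sy / sigma_yy``; LMG combines the subset
    gains with Shapley weights.  ``y`` is the last row/column.  Singular
    subset covariances fall back to the generalized inverse with a warning.
    """
    from .cvlmg import _shapley_coefficients, _subset_members

    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("cov must be square")
    if not np.allclose(cov, cov.T):
        raise ValueError("cov must be symmetric")
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-8 * max(1.0, np.abs(cov).max()):
        raise ValueError("cov must be positive semi-definite")
    m = cov.shape[0] - 1
    sigma_yy = cov[m, m]
    r2 = np.empty(1 << m)
    flagged = False
    for s, members in enumerate(_subset_members(m)):
        if members.size == 0:
            r2[s] = 0.0
            continue
        sub = cov[np.ix_(members, members)]
        cross = cov[members, m]
        try:
            sol = np.linalg.solve(sub, cross)
        except np.linalg.LinAlgError:
            sol = np.linalg.pinv(sub) @ cross
            flagged = True
        r2[s] = cross @ sol / sigma_yy
    if flagged:
        warnings.warn("singular subset covariance: generalized inverse used")
    C = _shapley_coefficients(m)
    return C @ r2
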