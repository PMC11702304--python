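"""End-to-end orchestration: simulate, detect epicentres, decompose, compare.

The stages mirror the study design: the patient cohort is split once into a
one-third *selection* sample — used only to locate the maximal-pathology
sites (epicentre proxies) — and a two-thirds *regression* sample feeding the
cross-validated decomposition, so epicentre choice never sees the regression
data.  All stage functions operate on in-memory objects; :func:`run_pipeline`
wires them to the on-disk dataset layout written by :func:`simulate_dataset`
and records a reproducibility manifest (config hash, seed, versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cvlmg import RelativeImportance, partition_cohort, make_splits
from .networks import WeightedGraph, assemble_predictors, retain_regions, \
    structural_group_network, functional_group_network
from .parcellation import Parcellation
from .statmaps import (
    EpicentreSet,
    compute_wscore,
    find_peaks,
    fit_wscore_model,
    one_sample_tmap,
    peaks_to_epicentres,
    threshold_tmap,
)
from .volume import VolumeGrid

__all__ = [
    "PipelineConfig",
    "simulate_dataset",
    "load_dataset",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Thresholds, regression settings and seeds for a pipeline run.

    Defaults follow the reference analysis settings (Bonferroni alpha 0.05,
    cluster extent k = 50 voxels, uncorrected fallback p < 0.001, minimum
    parcel size 100 voxels, FDR q = 0.05, Ridge penalty 1, 95% CIs) with
    desk-scale split/bootstrap counts; ``full_scale()`` returns the
    full-size preset (1000 splits, 10 000 replicates).
    """

    data_dir: str = ""
    output_dir: str = ""
    alpha: float = 0.05
    cluster_k: int = 50
    fallback_p: float = 0.001
    min_parcel_voxels: int = 100
    fdr_q: float = 0.05
    ridge_lambda: float = 1.0
    n_splits: int = 200
    n_boot: int = 2000
    ci: float = 0.95
    n_local_max: int = 3
    min_separation_mm: float = 8.0
    selection_fraction: float = 1 / 3
    seed: int = 0
    biomarker: str = "synthetic"
    covariate_columns: tuple[str, ...] = ("age", "education")

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.fallback_p < 1 and 0 < self.ci < 1):
            raise ValueError("thresholds out of range")
        if self.cluster_k < 1 or self.n_splits < 1 or self.n_boot < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def full_scale(cls, **kwargs) -> "PipelineConfig":
        kwargs.setdefault("n_splits", 1000)
        kwargs.setdefault("n_boot", 10_000)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "covariate_columns" in data:
            data["covariate_columns"] = tuple(data["covariate_columns"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_columns"] = list(self.covariate_columns)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def simulate_dataset(
    out_dir,
    seed: int = 0,
    n_regions_per_hemisphere: int = 30,
    grid_shape: tuple[int, int, int] = (40, 48, 40),
    n_basal: int = 2,
    n_controls: int = 20,
    n_patients: int = 40,
    network_subjects: int = 20,
    truth_spec: dict | None = None,
) -> dict:
    """Generate a full synthetic study and write it to ``out_dir``.

    Emits: atlas label NIfTI + parcellation JSON, 4D control/patient stacks,
    covariate TSV, structural count and functional correlation NPZ stacks,
    distance TSV and ``truth.json``.
    """
    from .synthetic import make_cohort, make_networks, make_parcellation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).spawn(3)
    parc = make_parcellation(n_regions_per_hemisphere, grid_shape, n_basal,
                             seed=np.random.default_rng(seeds[0]).integers(2**31))
    networks = make_networks(parc, subject_n=network_subjects,
                             seed=np.random.default_rng(seeds[1]).integers(2**31))
    controls, patients, covariates, truth = make_cohort(
        parc, networks, truth_spec, n_controls, n_patients,
        seed=np.random.default_rng(seeds[2]).integers(2**31),
    )

    vs = parc.label_volume.voxel_size_mm
    cio.save_parcellation(parc, out / "atlas.nii.gz", out / "parcellation.json")
    cio.save_stack(controls, vs, out / "controls.nii.gz")
    cio.save_stack(patients, vs, out / "patients.nii.gz")
    covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    np.savez_compressed(out / "struct_counts.npz", counts=networks.struct_counts)
    np.savez_compressed(out / "func_corr.npz", corr=networks.func_corr)
    cio.save_matrix_tsv(networks.distance, parc.region_ids, out / "distance.tsv")
    truth.to_json(out / "truth.json")
    return {
        "parcellation": parc,
        "networks": networks,
        "controls": controls,
        "patients": patients,
        "covariates": covariates,
        "truth": truth,
    }


def load_dataset(data_dir) -> dict:
    """Load a dataset directory written by :func:`simulate_dataset`."""
    d = Path(data_dir)
    parc = cio.load_parcellation(d / "atlas.nii.gz", d / "parcellation.json")
    controls, vs = cio.load_stack(d / "controls.nii.gz")
    patients, _ = cio.load_stack(d / "patients.nii.gz")
    covariates = pd.read_csv(d / "covariates.tsv", sep="\t")
    struct = np.load(d / "struct_counts.npz")["counts"]
    func = np.load(d / "func_corr.npz")["corr"]
    distance, dist_ids = cio.load_matrix_tsv(d / "distance.tsv")
    if not np.array_equal(dist_ids, parc.region_ids):
        raise ValueError("distance matrix region ids do not match the atlas")
    return {
        "parcellation": parc,
        "voxel_size_mm": vs,
        "controls": controls,
        "patients": patients,
        "covariates": covariates,
        "struct_counts": struct,
        "func_corr": func,
        "distance": distance,
    }


def _wscore_stack(dataset: dict, config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Patient W-maps (stacked) and the model validity mask."""
    cov_cols = list(config.covariate_columns)
    covs = dataset["covariates"]
    ctrl_cov = covs[covs["group"] == "control"][cov_cols].to_numpy(float)
    pat_cov = covs[covs["group"] == "patient"][cov_cols].to_numpy(float)
    vs = dataset["voxel_size_mm"]
    ctrl_grids = [VolumeGrid(v, vs) for v in dataset["controls"]]
    model = fit_wscore_model(ctrl_grids, ctrl_cov, cov_cols)
    wmaps = np.stack(
        [
            compute_wscore(model, VolumeGrid(v, vs), row).data
            for v, row in zip(dataset["patients"], pat_cov)
        ]
    )
    return wmaps, model.mask


def detect_epicentres(
    w_stack: np.ndarray,
    mask: np.ndarray,
    parcellation: Parcellation,
    config: PipelineConfig,
) -> EpicentreSet:
    """Selection-sample stage: group T-map, thresholding, peaks, epicentres."""
    vs = parcellation.label_volume.voxel_size_mm
    grids = [VolumeGrid(v, vs, mask) for v in w_stack]
    tmap = one_sample_tmap(grids)
    thresholded = threshold_tmap(tmap, config.alpha, config.cluster_k, config.fallback_p)
    peaks = find_peaks(thresholded, config.n_local_max, config.min_separation_mm)
    return peaks_to_epicentres(peaks, parcellation, config.biomarker)


def build_predictors(dataset: dict, epicentres: EpicentreSet, config: PipelineConfig):
    """Region retention, group networks and the nine-regressor matrix."""
    parc = dataset["parcellation"]
    vs = dataset["voxel_size_mm"]
    retained = retain_regions(parc, config.min_parcel_voxels, vs)
    ridx = np.array([parc.index_of(int(r)) for r in retained.region_ids])
    sub = np.ix_(np.arange(dataset["struct_counts"].shape[0]), ridx, ridx)
    struct = structural_group_network(
        dataset["struct_counts"][sub], retained, config.fdr_q
    )
    sub_f = np.ix_(np.arange(dataset["func_corr"].shape[0]), ridx, ridx)
    func = functional_group_network(dataset["func_corr"][sub_f], retained, config.fdr_q)
    dist = WeightedGraph(
        dataset["distance"][np.ix_(ridx, ridx)], retained, kind="distance"
    )
    return assemble_predictors(struct, func, dist, epicentres, config.biomarker)


def per_split_regional_tscores(
    w_stack: np.ndarray,
    mask: np.ndarray,
    parcellation: Parcellation,
    retained: Parcellation,
    strata,
    config: PipelineConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Regional T-score pairs for every train/test split of the regression sample.

    Per split and half, the voxel-wise one-sample t map across that half's
    W-maps is aggregated into the mean of positive t per retained parcel
    (within the analysis mask).
    """
    labels = parcellation.label_volume.data.astype(int)
    flat_mask = mask.ravel() & (labels.ravel() > 0)
    flat_labels = labels.ravel()[flat_mask]
    label_to_row = np.full(labels.max() + 1, -1, dtype=int)
    for row, rid in enumerate(retained.region_ids):
        label_to_row[int(rid)] = row
    rows = label_to_row[flat_labels]
    keep = rows >= 0
    w_flat = w_stack.reshape(w_stack.shape[0], -1)[:, flat_mask][:, keep]
    rows = rows[keep]
    n_regions = retained.n_regions

    plan = make_splits(np.arange(w_stack.shape[0]), strata,
                       config.n_splits, config.seed)

    def regional_t(sub: np.ndarray) -> np.ndarray:
        n = sub.shape[0]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        sd[sd == 0] = np.finfo(float).tiny
        t = mean / (sd / np.sqrt(n))
        pos = t > 0
        sums = np.bincount(rows[pos], weights=t[pos], minlength=n_regions)
        counts = np.bincount(rows[pos], minlength=n_regions)
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    pairs = []
    for train_ids, test_ids in plan:
        pairs.append((regional_t(w_flat[train_ids]), regional_t(w_flat[test_ids])))
    return pairs


def run_pipeline(config: PipelineConfig, dataset: dict | None = None) -> dict:
    """Execute partition -> epicentres -> predictors -> decomposition.

    Returns the result bundle (epicentres, predictors, results object) and, if
    ``config.output_dir`` is set, writes the JSON/TSV outputs plus a
    reproducibility manifest.
    """
    if dataset is None:
        dataset = load_dataset(config.data_dir)
    parc = dataset["parcellation"]
    covs = dataset["covariates"]
    patients_meta = covs[covs["group"] == "patient"].reset_index(drop=True)

    w_stack, mask = _wscore_stack(dataset, config)

    sel_idx, reg_idx = partition_cohort(
        patients_meta, "stage",
        (config.selection_fraction, 1 - config.selection_fraction),
        seed=config.seed,
    )
    epicentres = detect_epicentres(w_stack[sel_idx], mask, parc, config)
    if not epicentres.region_ids:
        raise RuntimeError("epicentre detection returned an empty set")

    predictors = build_predictors(dataset, epicentres, config)
    retained = predictors.parcellation

    strata = patients_meta.loc[reg_idx, "stage"].to_numpy()
    pairs = per_split_regional_tscores(
        w_stack[reg_idx], mask, parc, retained, strata, config
    )
    model = RelativeImportance(pairs, predictors, penalty=config.ridge_lambda)
    results = model.fit(n_boot=config.n_boot, ci=config.ci, seed=config.seed)

    bundle = {
        "epicentres": epicentres,
        "predictors": predictors,
        "results": results,
        "selection_n": int(len(sel_idx)),
        "regression_n": int(len(reg_idx)),
    }
    if config.output_dir:
        _write_outputs(bundle, config)
    return bundle


def _write_outputs(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.biomarker
    cio.save_epicentres(bundle["epicentres"], out / f"epicentres_{tag}.json")
    bundle["predictors"].to_tsv(out / f"predictors_{tag}.tsv")
    results = bundle["results"]
    results.estimate.to_json(out / f"lmg_{tag}.json")
    results.per_split_lmg.to_csv(
        out / f"per_split_lmg_{tag}.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    pd.DataFrame(
        results.estimate.per_region_lmg.T,
        index=bundle["predictors"].parcellation.region_ids.astype(int),
        columns=results.estimate.column_names,
    ).to_csv(out / f"per_region_lmg_{tag}.tsv", sep="\t",
             index_label="region_id", float_format="%.10g")
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "selection_n": bundle["selection_n"],
        "regression_n": bundle["regression_n"],
        "versions": _versions(),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "connshape": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
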