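"""Voxel-level statistics: W-scores, group T-maps, thresholding, peaks.

The analysis chain implemented here turns per-subject scalar volumes into
group-level abnormality maps and epicentre proxies:

1. a covariate-adjusted normative model is fitted voxel-wise on controls
   (:func:`fit_wscore_model`), giving each patient a W-score map — a Z-score
   adjusted for covariates such as age and education;
2. a one-sample t-test across patients' W-maps gives a group T-map
   (:func:`one_sample_tmap`);
3. the T-map is thresholded with a Bonferroni voxel cut-off plus a
   cluster-extent criterion (:func:`threshold_tmap`), with an uncorrected
   fallback when nothing survives;
4. the global maximum and up to three local maxima of the thresholded map
   (:func:`find_peaks`) are mapped to atlas regions, mirrored to their
   homotopic partners and cleaned of basal nuclei
   (:func:`peaks_to_epicentres`);
5. regional abnormality scores are the mean of positive T-values per parcel
   within a grey-matter mask (:func:`regional_scores`).

W-maps are oriented so that larger values mean more abnormal; all tests and
thresholds act on the positive tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .parcellation import Parcellation, RegionalVector
from .volume import VolumeGrid, stack_data

__all__ = [
    "WScoreModel",
    "StatMap",
    "Peak",
    "PeakSet",
    "EpicentreSet",
    "fit_wscore_model",
    "compute_wscore",
    "one_sample_tmap",
    "threshold_tmap",
    "find_peaks",
    "peaks_to_epicentres",
    "regional_scores",
    "group_mask",
]

# 6-neighbour (face) connectivity for cluster-extent thresholding.
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class WScoreModel:
    """Voxel-wise normative linear model fitted on controls.

    ``coefficients[0]`` is the intercept map; ``coefficients[1:]`` are one
    weight map per covariate.  ``residual_sd`` is the control residual SD with
    ddof equal to the number of fitted parameters.  Voxels where the control
    residual SD vanished are removed from ``mask``.
    """

    coefficients: np.ndarray          # (n_params, nx, ny, nz)
    residual_sd: np.ndarray           # (nx, ny, nz)
    covariate_names: list[str]
    grid: VolumeGrid                  # template carrying mask and voxel size
    mask: np.ndarray = field(default=None)  # valid-model voxels

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.grid.mask.copy()

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)


@dataclass
class StatMap:
    """A voxel-wise t-statistic map with degrees of freedom.

    ``threshold_applied`` records, if any: the per-voxel p cut-off, the
    cluster-extent minimum ``cluster_k`` and whether the cut-off was
    multiple-comparison corrected.
    """

    t_values: VolumeGrid
    df: int
    threshold_applied: dict | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass(frozen=True)
class Peak:
    voxel: tuple[int, int, int]
    t: float
    kind: str  # "global" or "local"


@dataclass
class PeakSet:
    """Ordered peaks (descending t): at most one global plus n local maxima."""

    peaks: list[Peak]

    def __post_init__(self) -> None:
        ts = [p.t for p in self.peaks]
        if ts != sorted(ts, reverse=True):
            raise ValueError("peaks must be ordered by descending t")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class EpicentreSet:
    """Atlas regions hosting the strongest group abnormality peaks.

    Closed under homotopic pairing and free of basal-nuclei regions.
    ``peak_stats`` keeps, for regions that directly contain a peak, the
    largest peak t landing in them.
    """

    region_ids: set[int]
    peak_stats: dict[int, float]
    biomarker_tag: str = ""

    def __len__(self) -> int:
        return len(self.region_ids)


def _design_matrix(covariates: np.ndarray | None, n_subjects: int) -> np.ndarray:
    if covariates is None or (hasattr(covariates, "shape") and covariates.size == 0):
        return np.ones((n_subjects, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n_subjects:
        raise ValueError(
            f"covariate rows ({cov.shape[0]}) != number of subjects ({n_subjects})"
        )
    return np.column_stack([np.ones(n_subjects), cov])


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in exact collinearity via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[diag < tol] if diag.size else []
    labels = ["intercept"] + list(names)
    return [labels[j] for j in sorted(bad)]


def fit_wscore_model(
    control_values,
    covariates=None,
    covariate_names: list[str] | None = None,
) -> WScoreModel:
    """Fit the voxel-wise normative regression on a control stack.

    Parameters
    ----------
    control_values : list of VolumeGrid or 4D ndarray
        One volume per control subject, row-aligned to ``covariates``.
    covariates : array-like (n_subjects, n_covariates) or None
        Covariate values (age, education, ...).  ``None`` or empty reduces the
        model to a per-voxel mean/SD, so W-scores become plain Z-scores.
    """
    data, template = stack_data(control_values)
    n = data.shape[0]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.size == 0:
            covariates = None
    n_cov = 0 if covariates is None else covariates.shape[1]
    if covariate_names is None:
        covariate_names = [f"cov{j}" for j in range(n_cov)]
    if n < n_cov + 2:
        raise ValueError(
            f"need at least n_covariates+2 = {n_cov + 2} controls, got {n}"
        )
    design = _design_matrix(covariates, n)
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        bad = _collinear_columns(design, covariate_names)
        raise ValueError(f"singular covariate design; collinear columns: {bad}")

    flat = data.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    # unbiased residual variance: ddof = number of fitted parameters
    sd = np.sqrt((resid**2).sum(axis=0) / (n - p))

    shape = template.shape
    sd_map = sd.reshape(shape)
    # a residual SD at rounding-noise level means the controls are exactly
    # linear in the covariates there: no usable normative variance
    sd_floor = 1e-10 * max(1.0, float(np.abs(flat).max()))
    valid = template.mask & (sd_map > sd_floor)
    n_degenerate = int((template.mask & ~valid).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} voxel(s) with zero residual SD flagged invalid "
            "and excluded from the model mask"
        )
    return WScoreModel(
        coefficients=beta.reshape((p,) + shape),
        residual_sd=sd_map,
        covariate_names=list(covariate_names),
        grid=template,
        mask=valid,
    )


def compute_wscore(
    model: WScoreModel, subject_values: VolumeGrid, covariates=None
) -> VolumeGrid:
    """W-map of one subject: (observed - covariate-predicted) / residual SD."""
    if subject_values.shape != model.grid.shape:
        raise ValueError(
            f"subject grid {subject_values.shape} != model grid {model.grid.shape}"
        )
    if covariates is None:
        covariates = []
    row = np.atleast_1d(np.asarray(covariates, dtype=float))
    if row.size != model.n_covariates:
        raise ValueError(
            f"expected {model.n_covariates} covariates, got {row.size}"
        )
    design_row = np.concatenate([[1.0], row])
    predicted = np.tensordot(design_row, model.coefficients, axes=1)
    w = np.zeros(model.grid.shape)
    m = model.mask
    w[m] = (subject_values.data[m] - predicted[m]) / model.residual_sd[m]
    return VolumeGrid(w, model.grid.voxel_size_mm, m.copy())


def one_sample_tmap(w_stack) -> StatMap:
    """Per-voxel one-sample t-test of W-maps against zero.

    t = mean / (sd / sqrt(n)) with df = n - 1.  Zero-variance voxels get
    +/-inf matching the sign of the mean (0 when the mean is 0) and are
    flagged with a warning.
    """
    data, template = stack_data(w_stack)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for a one-sample t-test")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & template.mask
    if degenerate.any():
        sign = np.sign(mean[degenerate])
        t[degenerate] = np.where(sign == 0, 0.0, sign * np.inf)
        warnings.warn(f"{int(degenerate.sum())} zero-variance voxel(s) in t-map")
    t[~template.mask] = 0.0
    return StatMap(
        t_values=VolumeGrid(t, template.voxel_size_mm, template.mask.copy()),
        df=n - 1,
    )


def threshold_tmap(
    statmap: StatMap,
    alpha: float = 0.05,
    cluster_k: int = 50,
    fallback_uncorrected_p: float = 0.001,
) -> StatMap:
    """Bonferroni + cluster-extent thresholding of a positive-tail T-map.

    The per-voxel one-tailed p cut-off is ``alpha`` divided by the number of
    in-mask voxels.  Surviving voxels are grouped into 6-connected components
    and components smaller than ``cluster_k`` voxels are removed.  If no voxel
    survives the corrected cut-off, the map is re-thresholded at the
    uncorrected ``fallback_uncorrected_p`` and the result is flagged
    ``corrected=False``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if cluster_k < 1:
        raise ValueError("cluster_k must be >= 1")
    grid = statmap.t_values
    n_mask = int(grid.mask.sum())
    if n_mask == 0:
        raise ValueError("empty analysis mask")

    def _apply(p_cut: float, corrected: bool) -> tuple[np.ndarray, dict]:
        t_crit = stats.t.isf(p_cut, statmap.df)
        supra = grid.mask & (grid.data > t_crit)
        labels, n_comp = ndimage.label(supra, structure=_FACE_STRUCTURE)
        if n_comp:
            sizes = np.bincount(labels.ravel())
            small = np.nonzero(sizes < cluster_k)[0]
            supra &= ~np.isin(labels, small[small > 0])
        record = {
            "voxel_p": p_cut,
            "t_crit": float(t_crit),
            "cluster_k": int(cluster_k),
            "corrected": corrected,
        }
        return supra, record

    supra, record = _apply(alpha / n_mask, corrected=True)
    if not supra.any():
        supra, record = _apply(fallback_uncorrected_p, corrected=False)
    out = np.where(supra, grid.data, 0.0)
    return StatMap(
        t_values=VolumeGrid(out, grid.voxel_size_mm, supra),
        df=statmap.df,
        threshold_applied=record,
    )


def find_peaks(
    statmap: StatMap, n_local_max: int = 3, min_separation_mm: float = 8.0
) -> PeakSet:
    """Global maximum plus up to ``n_local_max`` local maxima of a thresholded map.

    The global peak is the highest supra-threshold voxel.  Local maxima are
    voxels that are maxima of their 26-neighbourhood, taken in decreasing t
    order, each at least ``min_separation_mm`` from every already-accepted
    peak.  An empty map yields an empty :class:`PeakSet`.
    """
    if statmap.threshold_applied is None:
        raise ValueError("find_peaks expects a thresholded map")
    if n_local_max < 0:
        raise ValueError("n_local_max must be >= 0")
    grid = statmap.t_values
    supra = grid.mask & (grid.data > 0)
    if not supra.any():
        return PeakSet(peaks=[])
    vs = np.asarray(grid.voxel_size_mm)

    data = np.where(supra, grid.data, -np.inf)
    flat_order = np.argsort(data, axis=None)[::-1]
    coords = np.column_stack(np.unravel_index(flat_order, data.shape))
    n_supra = int(supra.sum())
    coords = coords[:n_supra]

    global_voxel = tuple(int(c) for c in coords[0])
    peaks = [Peak(global_voxel, float(data[global_voxel]), "global")]
    accepted_mm = [np.asarray(global_voxel) * vs]

    if n_local_max > 0:
        # 26-neighbourhood local maxima among supra-threshold voxels
        footprint = np.ones((3, 3, 3), dtype=bool)
        local_max = supra & (
            grid.data >= ndimage.maximum_filter(data, footprint=footprint)
        )
        for c in coords[1:]:
            if len(peaks) - 1 >= n_local_max:
                break
            c = tuple(int(x) for x in c)
            if not local_max[c]:
                continue
            pos = np.asarray(c) * vs
            if all(np.linalg.norm(pos - a) >= min_separation_mm for a in accepted_mm):
                peaks.append(Peak(c, float(data[c]), "local"))
                accepted_mm.append(pos)
    return PeakSet(peaks=peaks)


def peaks_to_epicentres(
    peaks: PeakSet,
    parcellation: Parcellation,
    biomarker_tag: str = "",
    max_reassign_voxels: int = 3,
) -> EpicentreSet:
    """Map peaks to atlas regions, add homotopic partners, drop basal nuclei.

    A peak falling in an unlabeled voxel is reassigned to the nearest labeled
    voxel within ``max_reassign_voxels`` (Euclidean, in voxels), otherwise the
    peak is dropped with a warning.  Duplicate regions collapse, keeping the
    largest peak t.  Basal-nuclei regions are removed *after* homotopic
    mirroring.
    """
    if parcellation.label_volume is None:
        raise ValueError("parcellation needs a label volume for peak assignment")
    labels = parcellation.label_volume.data.astype(int)
    known = set(int(i) for i in parcellation.region_ids)

    peak_stats: dict[int, float] = {}
    for peak in peaks:
        region = int(labels[peak.voxel])
        if region == 0 or region not in known:
            region = _nearest_labeled(labels, peak.voxel, known, max_reassign_voxels)
            if region is None:
                warnings.warn(
                    f"peak at {peak.voxel} not within {max_reassign_voxels} voxels "
                    "of any labeled region; dropped"
                )
                continue
        peak_stats[region] = max(peak_stats.get(region, -np.inf), peak.t)

    selected = set(peak_stats)
    for r in list(selected):
        selected.add(int(parcellation.homotopic[r]))
    selected = {r for r in selected if not parcellation.basal_nuclei.get(r, False)}
    peak_stats = {r: t for r, t in peak_stats.items() if r in selected}
    return EpicentreSet(
        region_ids=selected, peak_stats=peak_stats, biomarker_tag=biomarker_tag
    )


def _nearest_labeled(
    labels: np.ndarray, voxel: tuple[int, int, int], known: set[int], radius: int
) -> int | None:
    lo = [max(0, v - radius) for v in voxel]
    hi = [min(s, v + radius + 1) for v, s in zip(voxel, labels.shape)]
    best, best_d = None, np.inf
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    for idx in np.argwhere(sub > 0):
        coord = idx + np.asarray(lo)
        lab = int(labels[tuple(coord)])
        if lab not in known:
            continue
        d = np.linalg.norm(coord - np.asarray(voxel))
        if d <= radius and d < best_d:
            best, best_d = lab, d
    return best


def regional_scores(
    statmap: StatMap, parcellation: Parcellation, gm_mask: VolumeGrid | None = None
) -> RegionalVector:
    """Mean of strictly positive T-values per parcel within the grey-matter mask.

    Regions with no positive voxel (or an empty parcel-mask intersection,
    which triggers a warning) score 0, keeping the vector dense.
    """
    if statmap.threshold_applied is not None:
        raise ValueError("regional_scores expects an unthresholded map")
    if parcellation.label_volume is None:
        raise ValueError("parcellation needs a label volume")
    labels = parcellation.label_volume.data.astype(int)
    t = statmap.t_values.data
    mask = statmap.t_values.mask.copy()
    if gm_mask is not None:
        if gm_mask.shape != t.shape:
            raise ValueError("grey-matter mask grid mismatch")
        mask &= gm_mask.mask & (gm_mask.data > 0)

    values = np.zeros(parcellation.n_regions)
    empty_regions = []
    for k, rid in enumerate(parcellation.region_ids):
        in_parcel = (labels == int(rid)) & mask
        if not in_parcel.any():
            empty_regions.append(int(rid))
            continue
        vox = t[in_parcel]
        pos = vox[vox > 0]
        values[k] = pos.mean() if pos.size else 0.0
    if empty_regions:
        warnings.warn(
            f"{len(empty_regions)} region(s) with empty parcel-mask "
            f"intersection scored 0: {empty_regions[:10]}"
        )
    return RegionalVector(values=values, name="regional_t", parcellation=parcellation)


def group_mask(prob_stack, threshold: float = 0.3) -> VolumeGrid:
    """Boolean mask where the mean tissue probability exceeds ``threshold``."""
    data, template = stack_data(prob_stack)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability values must lie in [0, 1]")
    mean = data.mean(axis=0)
    mask = mean > threshold
    return VolumeGrid(mean, template.voxel_size_mm, mask)
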