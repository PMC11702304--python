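"""Comparison of two cohorts: Welch maps, epicentre pairing, permutation tests.

Built for contrasts such as risk-allele carriers versus non-carriers:

* :func:`welch_map` — voxel-wise two-tailed Welch t-test between the groups'
  W-map stacks (Satterthwaite degrees of freedom);
* :func:`equalize_epicentre_counts` — when the two groups' thresholded maps
  yield different numbers of peaks, the deficient group's map contributes its
  next-ranked maxima (the second global maximum and related local maxima)
  until the counts match;
* :func:`pair_epicentres` — epicentre regions of the two groups paired by
  rank of their peak statistics;
* :func:`levene_test` — equality of variances of the regional scores at the
  paired sites (classic mean-centred Levene);
* :func:`fisher_pitman` — two-tailed permutation test on the difference of
  group means, exact when the number of arrangements is small;
* :func:`compare_contributions` — permutation comparison per comparable
  regressor, Bonferroni-corrected.  The default unit is the per-region LMG
  allocation with a paired (sign-flip) Fisher–Pitman null, which is
  calibrated for a cohort-level null; the pooled per-split variant is kept
  as a sensitivity option.  Only structural/functional regressors
  significant (non-negative CI lower bound) in at least one group are
  compared; cortical-distance confounds never are.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .statmaps import EpicentreSet, StatMap, find_peaks, peaks_to_epicentres
from .volume import VolumeGrid, stack_data
from .cvlmg import LMGEstimate
from .networks import CONFOUND_COLUMNS

__all__ = [
    "GroupResult",
    "welch_map",
    "equalize_epicentre_counts",
    "pair_epicentres",
    "levene_test",
    "fisher_pitman",
    "paired_region_permutation",
    "compare_contributions",
]

#: exact enumeration is used when C(nA+nB, nA) does not exceed this
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class GroupResult:
    """Per-regressor group-comparison statistics with Bonferroni correction."""

    table: pd.DataFrame  # regressor, statistic, p_raw, p_corrected, p_product
    n_comparisons: int
    note: str = ""

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "n_comparisons": self.n_comparisons,
            "note": self.note,
            "comparisons": self.table.reset_index()
            .rename(columns={"index": "regressor"})
            .to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def welch_map(stack_a, stack_b) -> tuple[StatMap, VolumeGrid]:
    """Voxel-wise two-tailed Welch t-test between two W-map stacks.

    Returns the t-map (with the *minimum* in-mask Satterthwaite df recorded,
    the per-voxel df being available on the returned p-grid's metadata) and a
    two-tailed p-value grid.  Voxels with zero variance in both groups score
    t = 0, p = 1.
    """
    a, template_a = stack_data(stack_a)
    b, template_b = stack_data(stack_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group stacks must share one grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    mask = template_a.mask & template_b.mask

    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degenerate = (va == 0) & (vb == 0)
    t[degenerate] = 0.0
    df[degenerate] = na + nb - 2
    if (degenerate & mask).any():
        warnings.warn(
            f"{int((degenerate & mask).sum())} zero-variance voxel(s) set to t = 0"
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 1.0
    t[~mask] = 0.0
    p[~mask] = 1.0

    df_min = int(np.floor(df[mask].min())) if mask.any() else na + nb - 2
    tmap = StatMap(
        t_values=VolumeGrid(t, template_a.voxel_size_mm, mask), df=max(df_min, 1)
    )
    pgrid = VolumeGrid(p, template_a.voxel_size_mm, mask)
    return tmap, pgrid


def equalize_epicentre_counts(
    map_a: StatMap,
    map_b: StatMap,
    parcellation,
    n_local_max: int = 3,
    min_separation_mm: float = 8.0,
    biomarker_tag: str = "",
) -> tuple[EpicentreSet, EpicentreSet]:
    """Epicentre sets of two thresholded maps with equalized peak counts.

    Both maps are first given their usual 1 global + up to ``n_local_max``
    local peaks.  If the resulting epicentre sets differ in size, the
    deficient map contributes additional next-ranked maxima (its following
    global/local peaks in descending t order) until the set sizes match or
    its maxima are exhausted (warning).
    """
    for sm in (map_a, map_b):
        if sm.threshold_applied is None:
            raise ValueError("both maps must be thresholded")

    def extract(sm: StatMap, n_extra: int) -> EpicentreSet:
        peaks = find_peaks(sm, n_local_max + n_extra, min_separation_mm)
        return peaks_to_epicentres(peaks, parcellation, biomarker_tag)

    set_a = extract(map_a, 0)
    set_b = extract(map_b, 0)
    for _ in range(64):
        if len(set_a) == len(set_b):
            return set_a, set_b
        if len(set_a) < len(set_b):
            grown = _grow(map_a, set_a, parcellation, n_local_max,
                          min_separation_mm, biomarker_tag, len(set_b))
            if grown is None:
                break
            set_a = grown
        else:
            grown = _grow(map_b, set_b, parcellation, n_local_max,
                          min_separation_mm, biomarker_tag, len(set_a))
            if grown is None:
                break
            set_b = grown
    if len(set_a) != len(set_b):
        warnings.warn(
            "could not equalize epicentre counts "
            f"({len(set_a)} vs {len(set_b)}); proceeding with unequal sets"
        )
    return set_a, set_b


def _grow(
    statmap, current, parcellation, n_local_max, min_separation_mm, tag, target
):
    """Extend an epicentre set with the map's next-ranked maxima, if any."""
    for extra in range(1, 64):
        peaks = find_peaks(statmap, n_local_max + extra, min_separation_mm)
        grown = peaks_to_epicentres(peaks, parcellation, tag)
        if len(grown) > len(current):
            return grown
        if len(peaks) < 1 + n_local_max + extra:
            return None  # maxima exhausted
    return None


def pair_epicentres(
    set_a: EpicentreSet, set_b: EpicentreSet
) -> list[tuple[int, int]]:
    """Pair epicentre regions across groups by rank of their peak statistics.

    Regions of each set are sorted by descending peak statistic (regions
    without a direct peak — homotopic mirrors — use their partner-side rank
    value of -inf and sort last); ties break on the lower region id.  Unequal
    sizes pair up to the smaller set with a warning.
    """
    def ranked(es: EpicentreSet) -> list[int]:
        return sorted(
            es.region_ids,
            key=lambda r: (-es.peak_stats.get(r, -np.inf), r),
        )

    ra, rb = ranked(set_a), ranked(set_b)
    if len(ra) != len(rb):
        warnings.warn(
            f"pairing unequal epicentre sets ({len(ra)} vs {len(rb)}); "
            "pairing up to the smaller size"
        )
    return list(zip(ra, rb))


def levene_test(scores_a, scores_b) -> tuple[float, float]:
    """Classic (mean-centred) Levene test of equal variances.

    Returns (statistic, p).  Two identical constant groups give (0, 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0
    stat, p = stats.levene(a, b, center="mean")
    return float(stat), float(p)


def fisher_pitman(
    contribs_a,
    contribs_b,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-tailed Fisher–Pitman permutation test on the difference of means.

    The statistic is ``mean(A) - mean(B)``.  The null distribution permutes
    group labels over the pooled values: exhaustively when the number of
    arrangements C(nA+nB, nA) is at most :data:`EXACT_ENUMERATION_LIMIT`,
    otherwise by ``n_perm`` Monte-Carlo draws with the add-one estimator
    (the observed arrangement counts as one).  p is the proportion of
    arrangements with |null statistic| >= |observed|.
    """
    a = np.asarray(contribs_a, dtype=float)
    b = np.asarray(contribs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    total = pooled.sum()
    n_arrangements = math.comb(na + nb, na)

    def stat_from_sum_a(sum_a: float) -> float:
        return sum_a / na - (total - sum_a) / nb

    if n_arrangements <= EXACT_ENUMERATION_LIMIT:
        count = 0
        for pick in combinations(range(na + nb), na):
            s = stat_from_sum_a(pooled[list(pick)].sum())
            if abs(s) >= abs(observed) - 1e-12:
                count += 1
        p = count / n_arrangements
    else:
        rng = np.random.default_rng(seed)
        picks = np.argsort(rng.random((n_perm, na + nb)), axis=1)[:, :na]
        sums = pooled[picks].sum(axis=1)
        null_stats = sums / na - (total - sums) / nb
        count = int((np.abs(null_stats) >= abs(observed) - 1e-12).sum())
        p = (count + 1) / (n_perm + 1)
    return float(observed), float(p)


def paired_region_permutation(
    alloc_a: np.ndarray,
    alloc_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fisher–Pitman permutation on paired per-region LMG allocations.

    Both cohorts allocate their LMG contribution over the *same* regions, so
    the region is the paired exchangeable unit.  The statistic is the
    difference of the groups' contributions (the sum over regions of the
    per-region differences); the null swaps the group labels within random
    region pairs (sign flips of the differences).  Two-tailed, add-one
    estimator.
    """
    d = np.asarray(alloc_a, dtype=float) - np.asarray(alloc_b, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need per-region allocations of at least 2 regions")
    observed = d.sum()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    null_stats = signs @ d
    count = int((np.abs(null_stats) >= abs(observed) - 1e-12).sum())
    return float(observed), (count + 1) / (n_perm + 1)


def compare_contributions(
    est_a: LMGEstimate,
    est_b: LMGEstimate,
    n_perm: int = 10_000,
    seed: int = 0,
    unit: str = "region",
) -> GroupResult:
    """Permutation comparison of LMG contributions between two cohorts.

    Comparable regressors are the structural/functional (non-confound)
    columns significant — CI lower bound >= 0 — in at least one group;
    cortical-distance confounds are never compared.  With ``unit="region"``
    (default) the test is the paired region-level Fisher–Pitman permutation
    (:func:`paired_region_permutation`), whose statistic is the difference of
    the two groups' LMG contributions and which is calibrated for a
    cohort-level null; ``unit="split"`` pools the per-split LMG values in an
    unpaired :func:`fisher_pitman` (splits are correlated pseudo-replicates,
    so this variant overstates evidence and is kept for sensitivity checks).
    Raw p-values are Bonferroni corrected by the number of comparisons; both
    min(1, p*k) and the raw product p*k are reported.
    """
    if est_a.column_names != est_b.column_names:
        raise ValueError("estimates must share one regressor set")
    if unit not in ("region", "split"):
        raise ValueError("unit must be 'region' or 'split'")
    if unit == "region":
        if est_a.per_region_lmg is None or est_b.per_region_lmg is None:
            raise ValueError("per-region LMG allocations required")
        if est_a.per_region_lmg.shape != est_b.per_region_lmg.shape:
            raise ValueError("cohorts must share one region set for pairing")
    elif est_a.per_split_lmg is None or est_b.per_split_lmg is None:
        raise ValueError("per-split LMG values required")
    comparable = [
        j
        for j, name in enumerate(est_a.column_names)
        if name not in CONFOUND_COLUMNS
        and (est_a.significant[j] or est_b.significant[j])
    ]
    if not comparable:
        return GroupResult(
            table=pd.DataFrame(
                columns=["statistic", "p_raw", "p_corrected", "p_product"]
            ),
            n_comparisons=0,
            note="no regressor significant in either group; nothing to compare",
        )
    k = len(comparable)
    rows = {}
    seeds = np.random.SeedSequence(seed).spawn(k)
    for child, j in zip(seeds, comparable):
        name = est_a.column_names[j]
        child_seed = int(np.random.default_rng(child).integers(2**31))
        if unit == "region":
            stat, p = paired_region_permutation(
                est_a.per_region_lmg[j], est_b.per_region_lmg[j],
                n_perm=n_perm, seed=child_seed,
            )
        else:
            stat, p = fisher_pitman(
                est_a.per_split_lmg[:, j], est_b.per_split_lmg[:, j],
                n_perm=n_perm, seed=child_seed,
            )
        rows[name] = {
            "statistic": stat,
            "p_raw": p,
            "p_corrected": min(1.0, p * k),
            "p_product": p * k,
        }
    table = pd.DataFrame(rows).T
    return GroupResult(table=table, n_comparisons=k)
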