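# connshape

**How much does each brain-network pathway shape the topography of a disease
biomarker?**

Neurodegenerative pathologies such as grey-matter atrophy, glucose
hypometabolism, and amyloid-β or tau deposition are not spatially random:
their regional topographies track the brain's structural and functional
connectomes. Several spreading mechanisms have been proposed — *nodal
stress* (hubs are intrinsically vulnerable), *network diffusion* (damage
accumulates along connection weights), and *propagation from epicentres*
(pathology radiates from maximally affected regions). `connshape`
quantifies how much each mechanism, acting on each network, contributes to
a biomarker's regional pattern, while controlling for plain cortical
distance.

It is written for imaging-neuroscience researchers who have (or simulate)
per-subject scalar volumes, subject-level connectome stacks, and an atlas,
and want out-of-sample, confidence-bounded variance decompositions rather
than in-sample regression weights.

## The model

Per region *i* of a retained bilateral parcellation, a biomarker T-score
*y_i* is regressed on *m* = 9 standardized predictors: nodal strength *s_i*
and the Laplacian diffusion mode *|u₂|_i* of the structural and functional
connectomes, topological proximity to the biomarker's epicentre proxies
through both connectomes, and the three cortical-distance analogues as
confounds. The model is Ridge regression with fixed penalty λ = 1 and no
intercept,

```
β̂_S = (X_Sᵀ X_S + λI)⁻¹ X_Sᵀ y_train ,
```

fitted on the training half of repeated stratified subject splits and
evaluated on the held-out half via the explained variance
`evar(S) = 1 − Σ(y_test − X_S β̂_S)² / Σ y_test²`.

The test R² is then partitioned by the Lindeman–Merenda–Gold (LMG)
decomposition — a Shapley value over explained variance — extended to the
cross-validated setting:

```
LMG_j = Σ_{S ∌ j}  |S|! (m−1−|S|)! / m!  ·  [ evar(S ∪ {j}) − evar(S) ]
```

Because the empty model predicts 0 on standardized data, `evar(∅) = 0`
exactly and the contributions telescope: `Σ_j LMG_j = R²_test` on every
split, to machine precision. Confidence intervals come from a cluster
bootstrap that resamples *regions* over cached per-region squared errors
(no refitting); a contribution is significant when its 95% CI lower bound
is non-negative. Two cohorts (e.g. risk-allele carriers vs non-carriers)
are compared by a paired region-level Fisher–Pitman permutation test on
the per-region LMG allocations.

## Worked example

```python
import numpy as np
from connshape.synthetic import make_parcellation, make_networks, make_regional_cohort
from connshape.cvlmg import RelativeImportance

parc = make_parcellation(seed=11)                 # 60 mirrored regions
nets = make_networks(parc, seed=12)               # connectome + distance stacks
scores, X, truth = make_regional_cohort(parc, nets, seed=13)

model = RelativeImportance.from_subject_scores(scores, X, n_splits=100, seed=13)
res = model.fit(n_boot=500, seed=13)
print(res.summary())
```

prints

```
Cross-validated Ridge LMG decomposition
========================================================================
Regions: 56    Splits: 100    Bootstrap: 500    Penalty: 1
Out-of-sample R2: 0.526  [0.025, 0.749]
------------------------------------------------------------------------
regressor                             contrib    [2.5%   97.5%]  sig
structural_proximity_to_epicentres      0.255    0.087    0.359    *
functional_proximity_to_epicentres      0.137   -0.094    0.215
structural_nodal_strength               0.052   -0.042    0.120
cortical_distance_path_length           0.027   -0.069    0.075
structural_diffusion_mode               0.021   -0.017    0.039
functional_diffusion_mode               0.020   -0.029    0.040
cortical_distance_nodal_strength        0.009   -0.017    0.021
cortical_distance_diffusion_mode        0.004   -0.009    0.010
functional_nodal_strength               0.000   -0.009    0.007
========================================================================
* contribution with non-negative CI lower bound
```

The cohort was generated with all signal on structural proximity to the
epicentres and region-level noise giving a population R² of 0.5; the
decomposition recovers that mechanism as the only significant contributor
(25.5% of variance against an analytic population value of 28.1% for this
draw), and the total out-of-sample R² of 0.526 brackets the generating 0.5.
Four regions were dropped by the retention rule (basal nuclei and their
partners), leaving 56.

The same analysis runs end-to-end from voxel data — W-score maps against a
covariate-adjusted control model, group T-maps with Bonferroni +
cluster-extent thresholding, epicentre proxies from the map's global/local
maxima mirrored to their homotopic partners — via the CLI:

```bash
connshape simulate --out study/ --seed 7
connshape decompose --data study/ --out results/ --n-splits 100 --n-boot 500 --seed 7
connshape compare --a results_carriers/ --b results_noncarriers/ --out compare.json
```

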