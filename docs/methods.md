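# Methods

This note documents the statistical procedures implemented in `connshape`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## From voxels to regional outcomes

**W-scores.** A normative linear model is fitted per voxel on controls:
value ~ intercept + covariates (typically age and education; additional
covariates such as total intracranial volume or a reference-region binding
estimate can be appended per biomarker). A patient's W-score is
(observed − predicted) / SD of the control residuals. The residual SD uses
ddof equal to the number of fitted parameters (unbiased residual
variance). Voxels whose control residual SD is at rounding-noise level
(below `1e-10 ×` the data magnitude) carry no usable normative variance
and are removed from the analysis mask. With no covariates the model
degenerates to a per-voxel mean/SD, making W-scores plain Z-scores.
W-maps are oriented so that larger = more abnormal.

**Group maps and thresholding.** The group abnormality map is the
one-sample t statistic of the patients' W-maps against zero
(df = n − 1). Thresholding is one-tailed on the positive tail: the
per-voxel p cut-off is α divided by the number of in-mask voxels
(Bonferroni, default α = 0.05), followed by a cluster-extent criterion of
k ≥ 50 voxels (168.75 mm³ at the default 1.5 mm isotropic grid) on
6-connected (face-adjacency) components — the conservative, standard
connectivity for cluster-extent correction. If no voxel survives the
corrected cut-off the map is re-thresholded at an uncorrected p < 0.001
and flagged accordingly. The one-tailed choice follows from the
positive-abnormality orientation of the W-maps and from the downstream
regional aggregation, which keeps positive t-values only.

**Epicentre proxies.** The thresholded map's global maximum plus up to
three local maxima (26-neighbourhood maxima, each at least 8 mm from every
already-accepted peak; the separation is configurable, 8 mm matching
common cluster-table conventions) are mapped to atlas regions. Each
selected region's homotopic partner is added, then basal-nuclei regions
are removed; the set is therefore closed under homotopy except where a
basal exclusion removes a pair. Peaks in unlabeled voxels are reassigned
to the nearest labeled voxel within 3 voxels or dropped with a warning.

**Regional T-scores.** Per retained parcel, the mean of strictly positive
t-values over the parcel ∩ grey-matter-mask voxels; a parcel with no
positive voxel scores 0 rather than missing, keeping the regional vector
dense for the regression.

## Networks and predictors

**Region retention.** Basal nuclei and parcels smaller than 100 voxels
(337.5 mm³ at 1.5 mm) are dropped together with their homotopic partners,
so the retained set stays bilateral.

**Structural connectome.** Edge presence (streamline count > 0) across
subjects is tested with an exact one-sided binomial sign test against
chance 0.5 — the null that a connection is reconstructed no more often
than not — with Benjamini–Hochberg FDR at q = 0.05 over all edges.
Surviving edges are weighted by the across-subject mean of count divided
by the mean volume of the two regions (volume normalization removes
region-size bias).

**Functional connectome.** Subject correlation matrices (Ledoit–Wolf
shrunk covariance converted to correlation, via scikit-learn) are Fisher
z-transformed per edge and tested one-tailed (positive) with a one-sample
t-test, BH-FDR masked; the group matrix is the element-wise mean of the
raw subject correlations (not back-transformed mean z — the group weight
is an average correlation) with non-significant edges zeroed. Surviving
negative means are clipped to 0 because the graph metrics require
nonnegative weights; zero-variance edges count as significant when their
common z is positive.

**Graph metrics.** Nodal strength is the row sum of weights. The
diffusion mode is the unsigned eigenvector of the smallest strictly
positive eigenvalue of the *unnormalized* Laplacian L = D − W (no
normalization is implied by the diffusion-model formulation this metric
comes from), computed per connected component with per-component modes
summed into one vector; the eigenvector's sign pattern before the
absolute value defines the two diffusion clusters. For the
hemisphere-disconnected cortical-distance network this rule yields
exactly the sum of the two per-hemisphere modes. Topological proximity
inverts connectivity weights into lengths, runs Dijkstra
(`scipy.sparse.csgraph`), and takes the inverse of the mean shortest-path
length to the epicentre set; a region's zero distance to itself is
included in the mean. Degenerate case: a region that is the sole
epicentre has mean distance 0; its proximity is capped at the maximum
finite proximity in the map, keeping the vector finite and
rank-preserving. Unreachable epicentres are excluded from the mean with a
warning — expected by construction for the inter-hemispheric distance
network. The cortical path-length confound is the mean shortest path over
the raw distance graph (larger = farther, deliberately not inverted); a
region reaching no epicentre at all receives the maximum finite mean
length in the map (the farthest plausible value) rather than 0, which
would wrongly mark it nearest.

**Predictor matrix.** Nine columns in fixed order — structural strength,
structural diffusion, functional strength, functional diffusion, distance
strength, distance diffusion, structural proximity, functional proximity,
cortical path length — each rescaled to mean 0, SD 1 (population SD).
The three distance-derived columns are flagged as confounds: they are
fitted and decomposed like the others but never entered into group
comparisons. Strength and diffusion for the distance network are computed
on inverted distances (affinities). Multicollinearity is summarized by
VIFs (1/(1 − R²) of each column on the rest).

## Cross-validated Ridge LMG decomposition

Subjects of the regression sample are repeatedly split into stratified
half/half train/test sets (clinical stage as stratum; each split has its
own RNG stream derived from one seed). Per split, the training and test
regional T-scores are standardized with their own mean/SD (ddof 0); the
predictor matrix is standardized once globally, since it is fixed across
splits. Ridge with λ = 1 (the cited implementation's default, applied
identically to every subset model) and no intercept is fitted on the
training vector for every subset S of the nine regressors; the per-region
squared test errors for all 2⁹ = 512 subsets are cached as float32
(n_splits × 512 × n_regions).

The LMG contribution of regressor j in a split is the Shapley combination
over subsets, `Σ_{S∌j} w(|S|) [evar(S∪{j}) − evar(S)]` with
`w(k) = k!(m−1−k)!/m!` — mathematically identical to averaging sequential
gains over all 9! orderings and ~700× cheaper (the m! enumeration is kept
as a guarded oracle for m ≤ 8). Because the empty model predicts 0 and
the test vector is standardized, `evar(∅) = 0` holds exactly in floating
point, so the contributions telescope to the split's full-model test R²;
the residual error of the sum rule is bounded by coefficient rounding,
below 1e−10 in all tests. The point estimate is the mean over splits.

**Bootstrap.** CIs come from resampling *regions* with replacement
(the cluster unit: a region's test values and errors across all splits
and subsets move together), recomputing `evar` per subset and split from
the cache — no refitting — then recomputing per-split LMG vectors and
averaging. The interval is the 2.5/97.5 percentile over replicates (the
95% level); significance means a non-negative lower bound. Replicates
with zero test variance in any split are redrawn and logged. Out-of-bag
predictions are not used; this is a plain in-bag percentile bootstrap over
cached predictions. Desk-scale defaults are 200 splits / 2000 replicates,
configurable up to the full-scale 1000 / 10 000 preset.

## Group comparison

Voxel-wise differences between two cohorts' W-maps use a two-tailed Welch
t-test with Satterthwaite df. Epicentre counts are equalized by extending
the deficient group's map with its next-ranked maxima; sites are paired
across groups by rank of their peak statistics (ties break on the lower
region id), and Levene's test (classic, mean-centred — not the
median-centred Brown–Forsythe variant) compares the variance of regional
T-scores at paired sites.

LMG contributions are compared only for structural/functional regressors
significant in at least one group; distance confounds are never compared.
The default permutation unit is the **per-region LMG allocation**: since
the Shapley coefficients sum to zero over subsets, each split's
contribution decomposes exactly as `LMG_j = Σ_r a_jr` with
`a_jr = −Σ_S C_jS e_Sr / SST`, and the split-averaged `a_jr` allocate the
cohort's contribution over regions. Both cohorts allocate over the same
regions, so the region is a paired exchangeable unit; the test statistic
is the difference of the two cohorts' contributions and the null swaps
group labels within random region pairs (sign flips). This choice was
made after simulation showed that an unpaired permutation over pooled
per-split values — the only other replicated quantity — is grossly
anti-conservative for a cohort-level null: splits are correlated
pseudo-replicates of one cohort, their spread underestimates
between-cohort variance, and in a β = 0 simulation every comparison that
occurred produced a corrected p < 0.05. The paired region-level test is
calibrated in the same simulation (≈2% of seeds rejecting) while keeping
the statistic on the contribution-difference scale. The pooled per-split
variant remains available (`unit="split"`) for sensitivity analyses, and
the standalone `fisher_pitman` function implements the classic unpaired
test (exact enumeration up to 20 000 arrangements, otherwise Monte-Carlo
with the add-one estimator). Bonferroni correction multiplies by the
number of regressors actually compared; both min(1, p·k) and the raw
product are reported.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* a mirrored bilateral Voronoi parcellation with exact homotopic pairs,
  basal-nuclei flags and voxel-count volumes (default 30 regions per
  hemisphere on a 40×48×40 grid of 1.5 mm voxels);
* structural counts from a multiplicative nodal-gain model (lognormal
  gains; three designated homotopic hub pairs get a fixed dominant gain)
  modulated by module co-membership, spatial decay and strong homotopic
  edges, sparsified at the 35% quantile and scaled so kept edges have
  Poisson rates high enough for reliable per-subject presence; subject
  matrices are Poisson draws around the base times a lognormal subject
  gain;
* functional correlations from a per-subject noisy module-factor model,
  guaranteeing symmetric positive-definite matrices;
* distances as within-hemisphere shortest-path lengths on a neighbour
  graph of parcel centroids — metric within each hemisphere by
  construction, with no cross-hemisphere paths;
* cohorts whose regional pattern is p = Xβ + ε with ε ~ N(0, noise_sd²):
  X is computed from the generated networks and chosen epicentres
  (default: the first retained hub pair), β defaults to all mass on
  structural proximity with noise_sd = 1, giving population R² = 0.5 —
  a mid-range signal level where recovery is informative but not trivial.
  Patients add per-subject regional noise (SD 1) and, in the voxel
  generator, the pattern is painted uniformly over parcel voxels (scaled
  by 2 to give lesions of a few SD in W-score units) on top of voxel
  noise (SD 1) and linear age/education effects shared with controls.

The analytic recovery target is the population LMG computed from the
covariance of (X, y) with Σ_xy = Σ_xx β and σ²_y = βᵀΣ_xx β + noise_sd²,
via closed-form subset R² values and Shapley weights. Two cohorts "from
the same mixture" share the realized regional pattern — the pattern is
the population topography — and differ only in subject draws.

The generator does **not** emulate MRI/PET physics, spatial smoothing,
partial-volume effects, registration error, realistic atlas geometry, or
non-linear covariate effects. Passing recovery tests therefore shows that
the estimator chain is correct and well-calibrated under its own
assumptions, not that those assumptions hold in real imaging data.

## Problem sizes and runtime choices

Repeated simulation studies (parameter recovery, null calibration) run at
the regional level — per-subject regional score matrices rather than
painted voxels — which preserves the generative model while making
100-run studies take seconds each; the voxel path is exercised end-to-end
in the pipeline tests and the acceptance script. The recovery study uses
100 splits per run and reports the mean contribution (the bootstrap does
not enter the point estimate); null calibration uses 100 splits and 500
bootstrap replicates per cohort over 50 seeds. The subset-error cache
makes the bootstrap a pair of matrix products (counts-matrix trick), so
10 000 replicates at 228 regions remain feasible.

## Known limitations

* The Ridge penalty is fixed, not tuned; contributions inherit whatever
  bias λ = 1 induces (negligible shrinkage at n ≫ λ, but systematic).
* LMG contributions of correlated predictors share credit; a dominant
  generating mechanism leaks contribution into its correlates, so
  analytic and estimated values are compared per mechanism, not summed
  over "pathways".
* The paired region-level permutation test assumes per-region allocation
  differences are exchangeable in sign under the null; spatial
  autocorrelation between neighbouring regions is ignored (as it is in
  the region bootstrap).
* Epicentre detection feeds the predictor construction; with few
  selection subjects the fallback uncorrected threshold can admit noise
  peaks, propagating epicentre uncertainty that the bootstrap does not
  capture.
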