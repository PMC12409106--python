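# Methods

This note records the models behind each module, the defaults that matter,
the numerical choices made where the design was open, and what the
synthetic-data tests do and do not establish about real data.

## Spectral preprocessing

**Splice correction.** Field spectroradiometers stitch three detectors with
junctions near 990 and 1900 nm; mismatched gains leave multiplicative steps.
We rescale each downstream segment by the ratio of the upstream segment's
linear extrapolation (from its last two bands) to the observed value at the
first downstream band, processing joints left to right. A band exactly at a
joint belongs to the downstream segment. Linear extrapolation makes the
correction exact for locally linear spectra and is the standard
sensor-matching practice; constructed step artifacts are inverted to 1e-9.

**Resampling.** Linear interpolation onto an arithmetic grid (default 3 nm)
covering the input range. No smoothing is applied: the wavelet transform
that follows is itself a band-pass filter.

**Continuous wavelet transform.** Each spectrum is convolved with a
Mexican-hat (second-derivative-of-Gaussian) kernel at scales 2², 2⁴ and 2⁶
bands, and the three coefficient layers are summed bandwise. Kernels are
sampled over ±5 scale units, explicitly re-centered to zero mean (so
constants map to exactly zero despite discrete sampling) and L2-normalised
(so magnitudes are comparable across scales before summation). Edge handling
is reflect padding, chosen to avoid spurious extrema at the spectrum ends;
bands below 400 nm and above 2450 nm are trimmed *after* summation, since
the trim exists to drop low-SNR detector edges, not to change the transform.
The transform is linear and localizes an isolated Gaussian dip to within one
band of its center.

**Regions and indices.** VIS = [400, 700), NIR = [700, 1200),
SWIR = [1200, 2500] nm. Vegetation indices (CI = R750/R710,
NDWI = (R835−R1610)/(R835+R1610), ARI = 1/R550 − 1/R700) resolve their
wavelengths to the nearest band within half a grid step. Zero reflectance at
a required band yields NaN for that sample with a warning (or an exception
with `strict=True`), so one degenerate sample does not abort a batch.

## Chemometrics

PLSR and PLS-DA use NIPALS latent components (scikit-learn backend) with
centering only — wavelet coefficients share units, so per-band
unit-variance scaling would only amplify noise bands; it remains available
via preprocessing if inputs mix units.

**Component selection** minimizes cross-validated RMSEP with the
first-minimum-within-one-SE rule: the smallest component count whose CV
error is within one standard error (over folds) of the global minimum. On
pure-noise targets this collapses to one component.

**VIP.** VIP_j = sqrt(p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a), with SSY_a
the y-variance captured by component a (squared y-loading times score sum of
squares). Σ_j VIP_j² = p by construction. Band selection keeps VIP > 0.8,
then extends the set with VIP ≥ 0.4 to capture shoulders of discriminant
features.

**PLS-DA** iterates (default 50×): stratified 70/30 split, resample every
training class with replacement down/up to the smallest class size
(controls unequal sampling across species), fit one-hot PLS, classify
held-out samples by argmax of predicted class scores (ties break to the
lowest class index), and aggregate confusion counts. Rows of the confusion
matrix are predicted classes, columns observed; accuracy = trace/total;
Cohen's kappa, per-class sensitivity and specificity come from the
aggregated counts. Classes below 20 samples trigger a warning, not an
error.

## Neutral-marker statistics

**Weir–Cockerham θ (1984), multiallelic and multilocus**: per locus and
allele the a (among-population), b (among individuals within populations)
and c (within-individual) components are computed with the unequal-sample
size coefficients and summed; θ = Σa / Σ(a+b+c). Negative estimates are
reported as computed. Missing genotypes are handled per-locus complete-case
within the compared groups. The estimator is invariant to allele relabeling
and locus order; on a worked 2×2 toy table it equals the hand-derived
value 2/3.

**Bootstrap CI**: loci resampled with replacement (default 1000 draws),
percentile interval. With 20 loci its realized coverage at nominal 95% is
~91–93% in our calibration runs — the familiar mild anti-conservatism of
percentile intervals at small resample counts; it passes the ≥90%
validation threshold but users with few loci should prefer more loci over
more bootstrap draws.

**AMOVA** is a nested ANOVA on allele indicator variables with gene copies
as units (two per individual) — the infinite-alleles distance. Sums of
squares at the four levels (among species, among populations within
species, among individuals within populations, within individuals) are
computed from allele counts; variance components follow by method of
moments with the standard unbalanced nested-design coefficients;
percentages are components over their total. The MoM estimator is *not*
exactly invariant to duplicating every individual (degrees of freedom do
not scale with sums of squares); percentages move by a few points at n≈50
and converge with sample size. Permutation P-values (default 999) permute
populations across species, individuals across populations within species,
or gene copies among individuals within populations, according to the level
tested.

**Evanno ΔK** = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) over
replicate clustering log-probabilities; K* is the argmax. K values with
zero replicate sd are excluded with a warning. **Membership thresholding**
assigns a sample to its maximum-fraction cluster when that fraction meets
the threshold (0.6 for admixture-style output, 0.7 for spatial clustering
output), else flags it admixed. The clustering MCMC programs themselves are
out of scope; their outputs are inputs here.

## P_ST–F_ST

Variance components come from a one-way random-effects ANOVA by method of
moments: σ²_W = MS_within; σ²_B = max(0, (MS_between − MS_within)/n0) with
the standard unbalanced n0. The between-group component is truncated at
zero (the raw value can be recovered from the mean squares when needed).
P_ST(ratio) = ratio·σ²_B / (ratio·σ²_B + 2σ²_W) is strictly increasing in
the c/h² ratio with limits 0 and 1, so the selection decision is summarized
by the **critical ratio** — the smallest grid value at which the P_ST lower
confidence limit exceeds the F_ST upper limit — plus decision flags at the
anchors 0.25, 0.5, 0.75. The default grid is 40 log-spaced points in
[0.05, 2] plus the anchors.

The bootstrap resamples individuals with replacement *within* groups
(groups are fixed entities — species or populations), recomputing the whole
curve per replicate; CIs are percentile intervals. Under neutral
simulations the false-flag rate at ratio 0.25 stays below 10%; under a
3-SD standardized group difference against an F_ST ≈ 0.05 background, the
critical ratio falls at or below 0.25 in ≥ 90% of replicates. Band-level
scans use CWT coefficients as trait values, restricted to VIP-selected
bands; common-garden mode scans all supplied traits with VIP selection
disabled. c and h² are never separated — no heritability is estimated.

## IBD vs IBE variance partitioning

RDA is multivariate least squares of the centered response on a predictor
block; R² is the trace of the fitted sum of squares over the total, and
adjusted R² uses Ezekiel's correction with the block's rank. Partial RDA
residualizes response and predictors on the conditioning block; the
semipartial adjusted R² is adjR²(X∪Z) − adjR²(Z). The partition reports
a = pure ENV, c = pure GEO, b = joint (total − a − c) and the unexplained
remainder; negative fractions (possible with adjusted R²) are reported
as-is and flagged. Significance of a and c comes from free permutation of
reduced-model residuals (default 999), with a pseudo-F on the unadjusted R²
increment; the null distribution of these P-values is uniform in
calibration runs. Predictor screening: iterative VIF deletion (default
threshold 5, dropping the later column on ties) and greedy |r| ≤ 0.60
correlation filtering, which is order-dependent by construction — the
retained set depends on the input ordering, so configurations must list
variables in priority order. Spatial predictors default to centered
longitude/latitude, their squares and interaction; Moran eigenvector maps
are a documented alternative, not the default. The interface is
block-label agnostic: a genetic predictor block passes through identically.

## Phylogenetic signal and PGLS

Blomberg's K = (MSE0/MSE) / E_BM[MSE0/MSE], with MSE0 the mean squared
deviation from the phylogenetically weighted mean, MSE the BM-covariance
generalized mean squared error, and the expectation term
(tr V − n/(1'V⁻¹1))/(n−1). K is invariant to affine trait transforms. On
50-tip Yule trees, BM simulations calibrate to mean K ≈ 0.97 and white
noise to ≈ 0.2. Significance: tip-swap permutations give
P_WN = (1 + #{K_perm ≥ K_obs})/(n_perm + 1) (default 999 + observed — the
field reports both "1000 times" and "999 randomizations"; this default
covers both readings); a BM envelope (2.5–97.5 percentiles of simulated
traits rescaled to the observed tip variance, hence scale-free) flags
less-structured-than-BM traits. The per-band profile applies the same test
bandwise on population means, skipping constant bands, and annotates
VIS/NIR/SWIR regions.

PGLS solves the GLS normal equations by Cholesky whitening with the BM
shared-branch-length covariance (no Pagel's λ optimization); on a star
phylogeny it reduces exactly to OLS. Slope inference uses t with n−2 df.
An optional measurement-error extension (inflating the covariance diagonal
with within-tip squared SEs from `population_means`) is available but off
by default. Individual-level Pearson trait–environment correlations
complement the tip-level PGLS without phylogenetic correction.

## Synthetic data: what it emulates, and what it does not

Generators draw from one global seed fanned into fixed, named substreams,
so outputs are bit-reproducible and adding a generator never perturbs
existing streams.

- **Phylogenies**: Yule (pure-birth, rate 1) trees, exactly ultrametric.
- **Traits**: BM on the tree (tip covariance σ²·shared branch length);
  per-sample traits add within-population Gaussian noise around
  BM-positioned population means. Defaults mirror a dried-leaf survey: six
  structural/chemical traits with field-plausible means and SDs.
- **Genotypes**: Balding–Nichols — ancestral frequencies from a symmetric
  Dirichlet, population frequencies from Dirichlet(anc·(1−F)/F) — because
  it gives an analytic E[θ] ≈ F target without coalescent machinery. No
  microsatellite mutation model is implied.
- **Spectra**: smooth dried-leaf baseline minus Gaussian absorption
  features scaled by trait values, plus Gaussian noise, clipped to
  (0.001, 0.999). Feature centers sit in chemically sensible neighborhoods
  (pigments VIS, water/structure NIR, carbon chemistry SWIR) with loadings
  sized so features stay within the baseline (no clipping) while remaining
  recoverable at noise_sd = 0.005. This is *not* radiative-transfer
  physics: no PROSPECT-style scattering, no fresh/pressed calibration
  transfer.
- **Environment/geography**: population centers spread latitudinally
  (SD 5°) with individual scatter (SD 3°) so the spatial gradient retains
  within-population variation; each environmental variable =
  √ibe·(group effect) + √ibd·(standardized latitude) + √residual·noise.
  Group effects are orthogonalized against population-center coordinates —
  IBE is by definition environment-linked divergence independent of
  position — which keeps ibe = 1 environments exactly group-constant and
  makes the recorded shares recoverable by the partition to ±0.015 at
  n = 300.

Passing recovery tests on these generators shows the estimators are
correct and calibrated under their own assumptions (independent loci,
Gaussian traits, linear mixing, BM evolution). It does not show robustness
to linkage, null alleles, non-Gaussian traits, measurement drift between
instruments, or model misspecification in real herbarium data.

## Validation problem sizes

The validation suite (`spectraits.benchmarks`, reported by
`scripts/acceptance.py`) uses: F_ST recovery at targets 0.05/0.15/0.25 with
50 replicates of 4 populations × 30 diploids × 20 loci and CI coverage over
500 replicate datasets; 100 neutral and 50 divergent P_ST replicates with
300 bootstrap draws; PLSR/VIP on 200 samples at noise 0.005; PLS-DA on four
synthetic species × 30 samples; IBE/IBD recovery at n = 300 with 200
null-uniformity runs; 500 BM and 200 white-noise K draws on a 50-tip tree,
100 tip-swap type-I replicates, 20 spectral-profile replicates; 200 PGLS
slope-recovery simulations. These sizes were chosen to pin each statistic's
Monte-Carlo error well inside its acceptance tolerance while keeping the
full suite to about half a minute.

## Pipeline

`run_pipeline` executes preprocess → PLS-DA/PLSR → popgen → P_ST–F_ST →
variance partitioning → phylogenetic signal/PGLS from one flat YAML-backed
config (the analysis is a fixed DAG, so per-stage files would add nothing),
writing long-format delimited tables, a JSON summary, and a manifest with
the config hash and every stage seed; identical config + seed reproduces
byte-identical summaries. Stage failures halt with a stage-labeled error,
retaining partial outputs. The `spectraits` CLI is a thin layer over this
module: `simulate`, `validate`, per-stage verbs, and `run-all`.

## Known limitations

- AMOVA percentages can fall outside [0, 100] when components are negative
  (reported as computed, matching standard practice).
- The percentile locus bootstrap is mildly anti-conservative below ~25
  loci.
- Greedy correlation filtering is order-dependent; VIF deletion resolves
  ties by column position.
- PGLS assumes strict BM errors; no λ/OU transformations.
- P_ST inference conflates plasticity with genetic divergence unless
  applied to common-garden data; the c/h² sweep quantifies, but cannot
  remove, that assumption.
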