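# Methods

This note documents the models, the synthetic-data design, and the
numerical choices behind `ageatlas`, in the spirit of a statistical
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Gaussian-process age prediction

**Model.** Age is regressed on the subjects × ROI matrix of mean
gray-matter volume. Features are z-scored and the target centered using
*training-fold* statistics only (no leakage). The default covariance is
linear + bias + independent noise,

    K = σ_f² X Xᵀ + σ_b² 11ᵀ + σ_n² I,

the standard choice when the feature count (246 regions) rivals the sample
size; an additive RBF component (`kernel="linear+rbf"`, amplitude σ_f²,
length-scale ℓ) is available for nonlinear aging trajectories. All scales
are optimized on the log scale by Polak–Ribière conjugate gradients
(SciPy's `CG`), max 100 iterations, gradient tolerance 1e-6, from
σ_f = σ_b = 1, σ_n = 0.1·sd(y). The log marginal likelihood and its exact
gradient use the standard Cholesky expressions; a jitter of
1e-8·tr(K)/n is added before factorization, with one retry at 10×.

**Fast path.** For the linear kernel every likelihood evaluation is O(n)
after one eigendecomposition of X Xᵀ per fit: the bias term is a rank-one
update handled by Sherman–Morrison and the matrix-determinant lemma. This
is the same function as the dense evaluation (asserted to 1e-8 in the
suite) and is what makes the lesion analysis — ~18,000 GP fits at the
acceptance scale — run in minutes on one CPU. Because hyperparameters come
from an iterative optimizer, permuting subjects or feature columns changes
results only at the level of accumulated floating-point noise (observed
~1e-5 in MAE); invariance tests use tolerances of 1e-3 (MAE, years) and
1e-4 (r) rather than machine epsilon.

**Validation.** k-fold partitions are seeded permutations split into
blocks whose sizes differ by at most one; the repeat index extends the
seed, so partitions are reproducible and shareable. Headline metrics (MAE,
Pearson r, brain-PAD) are computed on the per-subject mean out-of-fold
prediction across repeats; per-repeat metrics are retained, since both
aggregation conventions appear in the brain-age literature. No
regression-to-the-mean correction of brain-PAD is applied. The sex test
residualizes brain-PAD on (1, age, age²) by least squares and compares the
residuals between sexes with a pooled-variance t-test; the TIV check is a
Pearson correlation with the t-transform p-value.

## Lesion analysis

Removing one network's columns and re-running the identical CV (same fold
partitions bit-for-bit, same initialization rule) isolates the lesion as
the only difference; lesioned hyperparameters are re-optimized, since a
"lesioned model" is a retrained model (reusing the full model's
hyperparameters would conflate the lesion with mis-specification — the
retrain choice is the default and the comparison is documented in output
metadata). The Z statistic is Steiger's (1980) test for two dependent
correlations sharing one variable, with the pooled-correlation covariance
approximation — the form used by standard correlation-comparison packages.
The sign convention reports positive Z when the lesion *degrades*
performance, so the importance ranking is by descending Z. p-values are
two-tailed normal and deliberately uncorrected across the 17 networks (the
ranking, not the family of tests, is the product). Z is computed on the
averaged out-of-fold predictions (primary) and as a per-repeat mean
(secondary, kept in the report).

## Transcriptomic annotation

Samples are represented by 6-mm spheres around their MNI coordinates;
voxel membership is by voxel-center distance in world coordinates. A
sample is admitted only when its sphere overlaps the background brain mask
by *strictly* more than 50% of sphere voxels, and is assigned to the
cluster (network) holding the largest share of sphere voxels; ties break
to the lowest cluster id with a logged warning. Expression is normalized
per donor and gene as (x − median)/median over that donor's samples —
donor scale cancels, and a zero median is a hard input error naming the
gene and donor. Probe-to-gene collapsing (highest mean expression) is
provided as a utility but the main path assumes gene-level input.

The association test is a permutation test on the mean normalized
expression of the in-cluster samples: the null redraws the same number of
samples uniformly without replacement from all admitted samples (cluster
labels exchangeable across the brain — the reading most consistent with
comparing against "random sample sets of the same size"), reusing one set
of permutations across genes. p-values use the add-one estimator
(1 + exceedances)/(n_perm + 1); the default is two-sided (direction is not
specified by "differentially expressed"), one-sided by flag. Family-wise
error control is single-step max-statistic by default — each gene's
|T_obs − null mean| against the permutation distribution of the maximum
across genes — which exploits the shared permutations and adapts to the
correlation structure; Bonferroni is available by flag. The adjusted p is
floored at the pointwise p so that p_FWE ≥ p holds exactly even in
discrete edge cases. Defaults: 999 permutations at desk scale, 5000 at
full scale, α = 0.05.

## Enrichment

A local over-representation analysis stands in for web-portal enrichment:
exact hypergeometric upper tail per GMT term with Benjamini–Hochberg FDR
(q < 0.05). The universe defaults to the genes measured in the expression
dataset — the actual background of the association test — rather than the
union of GMT terms. One-sided over-representation only, matching standard
pathway practice. Meta-database merging and term-similarity clustering are
out of scope.

## Synthetic data: what it emulates, and what it does not

**Atlas.** Voronoi growth from random seed voxels inside an ellipsoid
mask: the simplest deterministic construction yielding compact, contiguous,
space-filling parcels (Voronoi cells are convex, so their intersection
with the ellipsoid is connected). Networks are assigned round-robin over a
shuffled ROI order, balanced up to remainder. Defaults: 246 ROIs, 17
networks, 1.5-mm voxels on a 32×38×32 grid.

**Cohort.** For ROI j in network m, with per-subject latent aging offset
g_i ~ N(0, σ_g²) shared across ROIs:

    gmv_ij = b0_j + b1_j·(age_i + g_i + δ_sex·sex_i) + ε_ij,
    b1_j ~ N(slope_m, 0.05²),   ε_ij ~ N(0, σ_m²).

Ages are uniform on 19–80 (n = 492 by default; sex is a binary code,
0 = female, 1 = male, female fraction 306/492, with no GMV effect by
default). The offset g models stable individual differences in brain
aging and caps the achievable out-of-fold correlation at
sd(age)/√(sd(age)² + σ_g²); the default σ_g = 8.5 years places that
ceiling near 0.90, a realistic operating point for volumetric brain-age
models, chosen once from this closed form. Default slopes are shallow
(−0.08 to −0.12 units/yr, per-ROI noise sd 8) with the designated
important network boosted ×5 in slope and shrunk ×0.4 in noise — so age
information concentrates there while *every* network's mean GMV still
correlates clearly negatively with age. TIV is drawn N(1450, 110²) ml,
independent of the GMV residuals. Not modeled: nonlinear aging
trajectories, spatial autocorrelation of noise between neighboring ROIs,
scanner/site effects, education or other covariates. Passing tests
therefore certify the statistical machinery, not robustness to those
real-data complications.

**Expression.** Six donors with 363–946 samples each at full scale
(60–150 at desk scale); samples sit at voxel centers drawn uniformly in
the brain mask. Baseline per-gene expression is lognormal (log-location 1,
log-sd 0.25) with multiplicative sample noise (log-sd 0.25); signal genes
gain δ = 0.5 log-units in samples of the target network. Sample network
membership is defined by the *same* sphere-majority rule the annotation
stage applies, so generator truth and analysis agree on membership by
construction; the residual difference between planted and recovered genes
is then purely statistical. Not modeled: donor batch effects, probe-level
microarray structure, spatial expression gradients.

**Gene sets.** Random terms over the measured-gene universe, plus one
planted term containing all signal genes (padded to the minimum term
size). GMT-round-trippable.

## Scales

Two presets share every statistical rule and differ only in size:
`paper` (n = 492, 100 CV repeats, 5000 permutations, 20,738 genes,
363–946 samples/donor) and `desk` (n = 250, 5 repeats, 999 permutations,
500 genes, 60–150 samples/donor). The test suite and the acceptance script
run at desk scale; the sizes were fixed as the package's reference desk
conditions, and the methods above are scale-free.

## Known limitations

- The GP covariance in the original analyses is not fully specified
  upstream; the linear + bias kernel is the package's documented default,
  reported in output metadata, with `linear+rbf` as an alternative —
  neither is asserted to be "the" original choice.
- Steiger's Z is asymptotic; at small n (< ~50) its type-I error drifts
  from nominal. The null-calibration test runs at n = 200.
- The max-statistic FWE procedure assumes exchangeability of admitted
  samples across clusters; strong spatial autocorrelation of expression
  would weaken that assumption on real data.
- ROI means are unweighted arithmetic means over labeled voxels; no
  partial-volume weighting, and maps must already be on the atlas grid
  (no resampling — grid mismatches fail loudly).
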