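# Methods

## The model

`refusion` implements a supervised three-way fusion of multimodal
brain-imaging features.  Each of K modalities (functional connectivity
edge strengths, fractional anisotropy voxels, gray matter volume
voxels) is a subjects x features matrix X_k assumed to follow a linear
mixing model

    X_k = A_k S_k + E_k,

with subject loadings A_k, sparse spatial sources S_k and noise E_k.
A scalar per-subject reference — here the DNA-methylation beta-value of
one promoter CpG of NR4A1 — is hypothesized to covary with exactly one
*joint* component whose loading is shared across modalities and differs
between patients and controls.

### Canonical stage (multi-set CCA with reference)

Each modality is PCA-whitened to M dimensions, Y_k = (X_k − mean) F_k.
Weight matrices W_k (columns normalized in the within-modality
covariance metric, so canonical variates D_k = Y_k W_k have unit
variance and are mutually uncorrelated within a modality) maximize

    J = Σ_{i<j} Σ_{c=1..M} corr(D_i[:,c], D_j[:,c])²
        + λ Σ_k Σ_{c=1..M} corr(D_k[:,c], ref)² .

Squared correlations give a smooth, sign-free objective (the SSQCOR
flavor of multi-set CCA); λ trades inter-modality covariation against
reference alignment, with λ = 0 recovering plain multi-set CCA and
λ = 0.5 the default operating point.

**Optimization.** Deflationary alternating maximization.  For component
c, each modality's weight vector is updated in closed form as the top
eigenvector of a rank-(K−1+1) PSD matrix built from the cross-covariance
terms and the reference term, projected onto the covariance-orthogonal
complement of that modality's earlier components; the update provably
never decreases J, so the objective trace is non-decreasing and is
asserted to be so.  Initialization comes from the λ = 0 MAXVAR solution
(common subspace of the sphered modalities).  For K = 2, λ = 0 the
iteration is a power method on the cross-correlation operator and the
solution coincides with classical CCA (verified against the
generalized-eigenvalue formulation to 1e-6).  Convergence: change in
the per-component objective below `tol` (default 1e-6) within
`max_iter` (default 1000) sweeps; non-convergence is returned as
`converged=False` with a warning, never silently.  Components are
sorted by their contribution to J, descending.

All computations use exact covariances through a Cholesky transform of
each within-modality covariance (tiny ridge, 1e-12 x mean diagonal), so
the engine is also correct on inputs that are not exactly white — which
is what makes subject-wise cross-validation folds exact.

### ICA refinement (joint ICA)

The canonical maps of all modalities are concatenated feature-wise into
an M x Σp matrix and rotated toward independence.  The default
algorithm is natural-gradient infomax with a logistic nonlinearity
(appropriate for the super-Gaussian, sparse sources the mixing model
assumes), batch updates over all features, a fixed decaying
learning-rate schedule (0.05 / (1 + t/500)), halving on numerical
blow-up, seeded random orthogonal initialization, and a relative
weight-change stopping rule of 1e-6 within 5000 steps.
`fastica-logcosh` (scikit-learn) is available as an alternative
backend.  Gaussian sources make the rotation unidentifiable — runs
still converge numerically but the maps are arbitrary within the
Gaussian subspace.  Rotated maps are matched back to the canonical
ordering by greedy absolute-correlation assignment, scaled to unit SD,
and signed so the largest-magnitude entry is positive; sign and
permutation are the only indeterminacies tolerated against ground
truth.

Final subject loadings are least-squares projections of the prepared
data on the final maps, A_k = X_k C_kᵀ (C_k C_kᵀ)⁻¹ — i.e. group tests
are run on loadings of the *post-ICA* components, matching how joint
components are reported.

## Feature preparation

FC features are per-subject region-by-region Pearson correlations,
Fisher z-transformed (|r| clipped to 1 − 1e-7; raw r available) and
vectorized as the strict upper triangle in row-major order.  Age and
sex are regressed out of every modality, mean framewise displacement
out of FC only, by OLS with an intercept; residuals are checked
orthogonal to the covariates.  "Normalization for equal modality
contribution" is interpreted as per-feature centering plus division by
a single pooled SD per modality, so the modality's total variance is
one while its internal variance structure is preserved (per-feature
unit variance would change the relative weighting of features, which is
not what equal *modality* contribution asks for).

## Model order (MDL)

The number of components per modality is estimated by the Wax–Kailath
minimum description length criterion on the sample-covariance
eigenvalues,

    MDL(m) = −N (p−m) log(GM/AM of λ_{m+1..p}) + ½ m(2p−m) log N .

Two practical choices matter.  First, the candidate range stops at the
numerical rank: dimensions annihilated by centering or covariate
residualization carry zero eigenvalues that would otherwise dominate
the geometric mean.  Second, when features outnumber subjects (the
voxel-wise regime), subjects cannot serve as the sample index — the
trailing eigenvalues then follow a wide Marchenko–Pastur spread and the
sphericity term never flattens, driving the selected order to its
maximum.  The criterion is therefore applied in the orientation where
the larger dimension provides the samples (voxels as draws of a
subject-space vector, the convention of multivariate fusion toolkits);
since GM/AM is scale-invariant only N changes.  `n_effective` lets the
caller discount spatially smooth voxels.  The pipeline takes the
minimum of the per-modality estimates as the joint order (never below
2), and a fixed order can always be supplied instead.

## λ selection by cross-validation

Subject-wise k-fold CV (default 5 folds): for each λ on the grid
{0, 0.25, 0.5, 1}, weights are fit on the training folds and the
criterion is the mean over folds and modalities of |corr| between the
held-out top canonical variate and the held-out reference; ties resolve
toward the smaller λ.  CV of a guidance weight is informative exactly
when guidance has value: when the inter-modality signal alone already
identifies the reference-related component (moderate/high SNR), the
criterion is flat in λ and the choice is immaterial; when the signal is
noise-limited, the reference regularizes the weights and CV selects
λ > 0.  The CV test therefore exercises a noise-limited cohort.

## Statistics and component selection

Per (component, modality): Welch two-sample t-test on loadings (pooled
variance available; the unequal group SDs typical of patient/control
cohorts argue for Welch), Pearson correlation with the reference, and a
partial correlation after residualizing both loading and reference on
[intercept, group] (p from the t-transform with n − 3 df).  Group-test
and reference-test p-values are each Benjamini–Hochberg adjusted over
the full components x modalities family.  A component is *selected* in
a modality when both q-values fall below α = 0.05, and *jointly
selected* when selected in every modality; if several are, the one with
the smallest summed reference q is reported.  Loading/map signs are
aligned so the control mean exceeds the patient mean; a positive map
value then marks features reduced in patients.  Maps are z-scored over
features and displayed at |Z| > 3 (FC) or |Z| > 2 (voxel maps).
Clinical correlations (age of onset — patients only, MMSE, HSCT) are
Pearson with pairwise deletion of missing values.

Methylation: locus-wise Welch t-tests on beta-values in [0, 1] (M-value
logit transform optional), one BH adjustment across all loci, rows
ranked by q then |t|.  Note that BH produces exact q ties between loci
whose step-up bounds interleave, so "top-ranked by q" is a set that can
contain more than one locus.  Cross-assay validation is a plain Pearson
correlation of paired measurements.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not MRI physics.  One shared standard-normal latent drives the target
component: each modality's target loading is the latent plus small
modality noise (SD 0.2) minus `group_effect_d` x the patient indicator;
the reference is ρ_ref x the standardized latent plus independent
noise; clinical scores are noisy linear functions of the common target
loading at configured correlations (defaults 0.6 onset age, 0.4 MMSE,
0.3 HSCT, on realistic measurement scales; onset age is missing for
controls).  Non-target loadings are independent standard normals per
modality, so only the target carries cross-modality and reference
structure.  Sources are sparse Laplacian rows (default 15% nonzero) —
super-Gaussian, hence ICA-identifiable.  Defaults mirror the designed
study conditions: 33 patients / 40 controls, three modalities of
300/250/200 features, five sources, ρ_ref = −0.4 (higher methylation,
lower loading), group shift 0.8 SD (control > patient), noise SD 0.5.
The reference's marginal distribution is modeled as Gaussian latent
plus noise; the true distribution across subjects is unknown and no
claim is made that this matches a real cohort.

Methylation matrices are Beta(a, b) draws parameterized by mean/SD via
method of moments (respecting the [0, 1] support), with per-locus
baseline means uniform in [0.1, 0.9] shared by both groups and a mean
shift of `delta` (default 0.06: 0.34 patient vs 0.28 control, SD 0.06)
at the target loci.  In the demonstration of assay cross-validation,
the second assay is the array beta plus independent N(0, 0.025)
measurement noise — the noise level implied by a published cross-assay
correlation of ~0.9 at a between-subject SD of 0.06.

What the generator does **not** emulate — spatial autocorrelation of
brain maps, site/batch effects, realistic FC geometry, non-Gaussian
reference marginals, LD-like correlation between methylation loci —
bounds what passing tests show: they demonstrate correctness of the
algorithms under the model's own assumptions, not performance on real
MRI or BeadChip data.

## Subset replication

The identical pipeline is rerun on subsets: either R random subsamples
of floor(2/3) of each class (patients and controls subsampled
independently to preserve the class ratio; "two thirds" rounds down) or
explicit label-defined subsets (e.g. lateralization subgroups with
their matched controls, which the caller supplies — no matching
algorithm is implemented).  Each run's selected-component map is
compared to every other run by absolute spatial correlation (greedy
max-|r| matching absorbs ICA ordering; a run that selects no component
falls back to its best match against the full-cohort map), and an
overlap mask marks features surviving the z-threshold in at least two
runs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise: parameter recovery
on 100+100-subject, three-modality, five-source cohorts (20 and 10
seeded runs respectively); the CCA oracle at n = 60 over 50/25 seeds;
null calibration on 200/100 runs of 33+40-subject cohorts with
120/100/80 features; methylation testing at 1,000 loci; and replication
on a 120+120 cohort with R = 2 subsamples.  These sizes were chosen so
the whole battery completes in minutes on one core while keeping every
Monte-Carlo bound well-powered.

## Known limitations

* The reference must be complete: subjects with a missing reference
  value are dropped rather than imputed.
* One scalar reference only; no multi-reference or kernel variants.
* The MDL orientation correction treats features as i.i.d. samples;
  for spatially smooth real volumes an explicit `n_effective` should be
  supplied.
* The deflationary optimizer is greedy per component; it guarantees a
  monotone objective but, like all multi-set CCA schemes, not a global
  optimum.
* FDR q-value ties mean "the top locus" is in general a set, not a
  single locus.
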