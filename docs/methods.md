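# Methods

## Problem setting

After acute ischemic stroke, about one patient in six remains functionally
dependent at 90 days (modified Rankin Scale, mRS > 2). The working
hypothesis behind this package is that the *spatial texture* of the infarct
on the apparent diffusion coefficient (ADC) map — how heterogeneous the
lesion's voxel intensities are, beyond its size — carries prognostic
information that simple clinical covariates (age, NIHSS, risk factors,
lesion volume) do not. The package implements the complete analysis chain
needed to test that hypothesis: lesion texture quantification, sparse
feature selection, imbalance-aware classification, and the two-group
statistics used for clinical tables.

Because suitable patient imaging with 90-day outcomes is not publicly
redistributable, the package ships a first-class synthetic-data module that
generates both the clinical table and paired ADC/DWI lesion phantoms with a
*known, constructed* outcome–texture association, so every downstream stage
can be validated end to end with ground truth in hand.

## Preprocessing and quantization

Volumes and masks are NIfTI-1 files on identical voxel grids; the lesion
outline drawn on DWI is copied voxel-for-voxel onto the ADC map and no
resampling is ever attempted (a shape mismatch is an error). Intensities
are mapped to [0, 1] by a display window: `out = clip((in − (level −
width/2))/width, 0, 1)`. Window width/level are configuration inputs; by
default they are derived from the volume's min/max, since no universal ADC
window exists.

Masked voxels are discretized to `Ng` gray levels by fixed bin number:
`level = min(Ng, floor(Ng·(x − min)/(max − min)) + 1)` over the VOI, with a
constant VOI mapping to level 1. Default `Ng = 32`, a common radiomics
compromise between matrix sparsity (large `Ng`, small lesions) and
discrimination (small `Ng` washes out structure). Fixed-bin-number
quantization is invariant to affine intensity rescaling of the VOI, which
makes the texture features independent of the window choice.

## Texture features

All matrices are computed in 3D over voxel index space with the 13 unique
26-neighborhood directions (anisotropic spacing is ignored for neighbor
definitions, consistent with slice-stacked masks). Counts are summed over
directions and normalized once; the alternative per-direction averaging
differs only by weighting and would break the integer conservation
identities used as self-checks:

* GLCM: probabilities sum to 1;
* GLRLM: `Σ_{i,j} j·R[i,j] = N × 13` (every voxel lies in exactly one
  maximal run per direction);
* GLSZM: `Σ_{i,s} s·Z[i,s] = N` (zones partition the VOI);
* NGTDM: level probabilities over valid voxels sum to 1.

The 39-feature signature is 8 GLCM features (energy, contrast, correlation,
variance, homogeneity, entropy, dissimilarity, maximum probability — the
classic co-occurrence set), 13 GLRLM features (SRE, LRE, GLN, RLN, RP,
LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV), the 13 analogous GLSZM
features over 26-connected equal-level zones, and the 5 NGTDM features
(coarseness, contrast, busyness, complexity, strength, after Amadasun &
King). Degenerate denominators carry an `ε = 1e-12` guard and the
degenerate value of busyness/contrast/complexity/strength is 0; GLCM
correlation of a constant VOI is defined as 1. A VOI with fewer than 2
voxels or a single effective gray level gets defined fallback values (the
single-entry co-occurrence matrix) plus a `quality_flag`; flagged lesions
are excluded from modeling, mirroring the "feature extraction failure"
exclusions typical of clinical radiomics pipelines. Every implementation is
tested against independent brute-force enumeration oracles (pair counting,
run walking, flood fill, neighborhood averaging) on random small VOIs.

## Sparse-representation feature selection

Selection solves `ŵ = argmin_w ‖l − Fw‖² + η‖w‖₀` on standardized training
features with labels coded ±1. Exact L0 minimization is NP-hard, and no
solver is prescribed by the model itself, so the package uses greedy
orthogonal pursuit: add the column most correlated with the residual, refit
exact least squares on the support, stop when a step reduces the squared
residual by less than `η` (default 0) or the support reaches `k_max`
(default 10). A single-swap local refinement follows the greedy pass —
support and non-support columns are exchanged while the refit residual
improves — which never increases the residual and makes the solver agree
with exhaustive support enumeration on small well-conditioned designs,
where plain greedy pursuit can occasionally be trapped by coherent columns.
Rank-deficient candidate supports drop the offending column and continue.
Standardizing columns first makes |w_i| comparable across features, so the
final selection is simple magnitude thresholding (default threshold 0 =
the full support). Within the pipeline, selection sees *training rows
only*, so the validation set never leaks into the selected support, and the
stage runs after the split for exactly that reason.

## Cohort split and classifiers

The outcome is imbalanced (default prevalence 163/1003 ≈ 16.3%), so the
training set is built by under-sampling: `floor(2/3 · n_unfav)` unfavorable
patients train, the favorable training arm is `floor(1.5 ×)` that count
(sampled without replacement), and every remaining patient validates.
Floor rounding at both steps is the documented convention; for the
reference 163/840 cohort this gives 108 + 162 training and 733 validation
patients.

Two classifier families share one interface. The recurrent variant is a
single-layer GRU (hidden size 32) implemented in numpy with hand-derived
backpropagation-through-time gradients (verified against finite
differences in the test suite); the standardized feature vector is
presented as an ordered sequence of length-3 chunks, zero-padded at the
end. Training minimizes class-weighted sigmoid cross-entropy by Adam
(defaults lr 1e-4, batch 10, up to 300 epochs with early stopping after 25
epochs without training-loss improvement). Class weights default to
inverse class frequency, which removes the imbalance incentive to predict
the prior. The logistic baseline is a class-weighted logistic regression;
it is deterministic given the data and is the model used wherever
bit-reproducibility matters (pipeline reruns, the synthetic benchmark in
the acceptance script), since the scientific claim under test — texture
features outrank clinical covariates — concerns the feature signal, not
the classifier family.

## Two-group statistics

Clinical tables use Pearson chi-square without continuity correction for
categorical variables (the uncorrected statistic reproduces the published
2×2 outcome-table p-values 0.801 / 0.475 / 0.566 / 0.030 / 0.045 to three
decimals, which a Yates-corrected statistic does not), a pooled-variance
two-sample t-test for normal continuous variables (pooled, not Welch,
reproduces the published age comparison from its printed summaries), and
Mann–Whitney U otherwise. Normality is judged per group by Shapiro–Wilk at
α = 0.05. The Mann–Whitney exact path (n₁+n₂ ≤ 12) enumerates all label
assignments of the pooled sample, which remains exact under ties; the
large-sample path uses the tie-corrected normal approximation without
continuity correction. All p-values are two-tailed. The p < 0.05 texture
screen applies no multiple-testing correction — it mirrors the screening
convention of the clinical literature it emulates and is a known
limitation, flagged here deliberately: with 39 features about two false
positives are expected per null cohort, and the test suite checks exactly
that calibration. One published value does *not* reproduce: the 2×5
TOAST-subtype table yields p ≈ 0.005 by Pearson chi-square, not the
printed 0.012, so that row is documented rather than asserted.

## Evaluation

AUC is computed by the rank (Mann–Whitney) formulation with midrank ties
and is tested equal to the trapezoidal area under the empirical ROC curve.
Operating points default to Youden's J, with ties resolved toward the
highest (most specific) threshold; the published tables do not state their
threshold rule, so this is an explicit design choice, and a fixed-threshold
rule is available.

## Synthetic study conditions

The cohort generator reproduces the marginal structure of a 1003-patient
single-center cohort: outcome prevalence 163/1003; subtype mix LAA/CE/SAO/
Other/Undetermined = 544/80/298/13/68; binary covariate prevalences from
the pooled printed counts; age ~ N(65.9, 12.44²) years; LDL-C ~ N(3.02,
0.96²) mmol/L; NIHSS and stroke volume lognormal with log-scale parameters
(ln 3, 0.9) and (ln 1.68, 1.35) chosen to match the printed medians and
interquartile ranges. Covariate–outcome associations enter through a
logistic model whose intercept is calibrated by root finding so the
expected unfavorable fraction equals the target exactly; all default
log-odds are zero, matching the mostly null clinical differences of the
emulated cohort (admission NIHSS and stroke volume *do* differ in the
original population; modelling those two associations is deliberately left
to `association_spec` so that the default benchmark has a null clinical
arm and any clinical-model AUC above chance would be a bug, not a feature).

Phantoms are ellipsoids (semi-axes uniform in 2.5–7.0 mm, i.e. volumes of
roughly 0.07–1.4 ml, the same order as the printed stroke-volume medians)
on a 24×24×16 grid at 1 mm isotropic spacing — deliberately small so that
thousand-lesion cohorts extract in seconds; the texture statistics of a
stationary random field do not depend on the grid extent, only on its
correlation structure. Interior intensities are `base + contrast·sd·field
+ noise`, with `field` white Gaussian noise convolved with an isotropic
Gaussian kernel (σ = correlation length, in voxels) and rescaled to unit
variance. Favorable lesions default to correlation length 1.8 voxels and
contrast 1.0; unfavorable to 0.9 and 1.4 — rougher, higher-contrast
texture, the constructed analogue of "more heterogeneous" infarcts.
Unsmoothed voxel noise (sd 30 on a base sd of 100) is added separately so
that field smoothness and noise level can be varied independently; NGTDM
coarseness decreases as the noise amplitude grows, and GLCM contrast rises
as the correlation length shrinks, both verified by matched-seed
Monte-Carlo tests. The cohort table's `stroke_volume` is replaced by the
true phantom mask volume whenever images are simulated, so table and
images always agree.

What the phantoms do **not** emulate: brain anatomy, partial-volume edges,
scanner noise spectra, b-value decay, multi-scanner harmonization, or any
correlation between lesion *size* and outcome. Passing tests therefore
demonstrate that the pipeline recovers a texture signal that is present by
construction and stays calibrated when it is absent — not that such a
signal exists in real stroke imaging, nor how large it would be there.

## Numerical and reproducibility choices

Every stochastic stage derives a stable sub-seed from the single pipeline
seed by hashing a stage label (all sub-seeds < 2³¹), so stages are
independently reproducible and reruns with the logistic model are
bit-identical. The synthetic benchmark in the acceptance script uses
n = 1003 cohorts and a handful of replicates; the test suite uses 20
replicates for the AUC-ordering check and 200 replicates for the screening
calibration — sizes chosen so the whole suite runs in minutes on one CPU
while keeping the Monte-Carlo standard errors well inside the asserted
margins.

## Known limitations

* The L0 solver is a heuristic; exhaustive-equivalence is only guaranteed
  on the small designs the tests cover.
* The GRU is a minimal reference implementation (no gradient clipping, no
  validation-based early stopping); it is not tuned for performance parity
  with the logistic baseline on small cohorts.
* The feature screen's lack of multiplicity correction and the pretest
  routing via Shapiro–Wilk both follow clinical-table convention rather
  than statistical optimality.
* Real-data I/O supports exactly congruent grids only; registration and
  resampling are out of scope.
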