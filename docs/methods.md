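# Methods

`widedecode` implements a decoding framework for asking how much
stimulus-specific information a set of brain activity maps carries, where
in the brain it lives, and how it changes with the level of sedation.
This note records the models, the estimators, the synthetic-data
assumptions, and the numerical choices, in enough detail to reproduce or
audit any number the package computes.

## Decile decoders

The unit of analysis is a pair of activation-map stacks `B_I, B_NI ∈
ℝ^{n×p}` (n subjects, p voxels): per-subject GLM beta maps for a
condition of interest and of no interest. A voxel-wise paired t-test
gives a map `t ∈ ℝ^p` (df = n − 1; zero-variance voxels are assigned
t = 0 so the partition below stays total). Voxels are ranked by |t| and
split into 10 contiguous, near-equal bins ("deciles"; bin 10 = highest
|t|). Each bin becomes a linear decoder whose weights are the *signed*
t values of its member voxels and 0 elsewhere, so the full decoder
matrix is `D ∈ ℝ^{p×10}` and the column sums of the bins reconstruct the
complete signed-t map. Scores are plain dot products, `R_I = B_I D`,
`R_NI = B_NI D`, and each decile's discrimination is the Mann–Whitney
AUC between the two score columns (ties count 1/2; subjects are treated
as paired for decoder training but independent for testing).

Tie handling at bin boundaries uses a stable sort on (|t|, voxel index);
bin membership is therefore deterministic and invariant under any
strictly monotone transform of |t|.

## Floor-free 0.632+ bootstrap

Apparent performance (train = test = full sample) is optimistically
biased — on pure noise the top decile's apparent AUC approaches 1. The
0.632+ estimator corrects this: draw `b` bootstrap samples of subjects
with replacement (paired maps travel together), re-derive the t-map and
the decile partition *inside* each bootstrap sample, and evaluate on the
out-of-bag subjects (~36.8%). With `θ̂app` the apparent AUC and `θ̂•boot`
the mean out-of-bag AUC,

```
R̂ = 1                          if θ̂•boot ≤ 0.5
R̂ = (θ̂app − θ̂•boot)/(θ̂app − 0.5)   if θ̂app > θ̂•boot   (clamped to [0, 1])
R̂ = 0                          otherwise
ŵ = 0.632 / (1 − 0.368 R̂)
θ̂0.632+ = (1 − ŵ) θ̂app + ŵ θ̂•boot
```

The conventional floor `max(θ̂•boot, 0.5)` is deliberately **not**
applied: flooring would bias downstream variance estimates, and
estimates are allowed to dip below chance. Out-of-bag draws with fewer
than `min_oob` (default 2) test subjects are redrawn (with a logged
count). Per-replicate RNG substreams are spawned from the root seed by
counter, so results are bit-reproducible and independent of scheduling.

Variances and covariances across deciles come from a nested bootstrap:
the outer loop (default 500 replicates) resamples subjects, each outer
replicate runs the full inner 0.632+ procedure (default 100 replicates),
and the covariance is taken across the outer estimate vectors (50,000
inner evaluations at the defaults; tests and examples scale the loop
counts down to desk size).

## Summaries: squeezing, logit, covariance-weighted GLS

AUCs are shrunk toward 0.5 ("squeezed") before the logit transform to
avoid boundary singularities: `θ* = ((m − 1)θ + 0.5)/m` with m the
number of brains (twice the participants). Decile curves are summarized
by generalized least squares on the squeezed-logit AUCs with weight
matrix `W = Σ̂⁻¹`, where Σ̂ is the replicate covariance of the logit
AUCs — a full matrix, so between-decile dependence is accounted for
(unlike diagonal weighted least squares). Then

```
β̂ = (XᵀWX)⁻¹ XᵀWy,   SE[β̂] = sqrt(diag((XᵀWX)⁻¹)),
```

the sandwich collapsing to `(XᵀWX)⁻¹` exactly because W is the inverse
of the assumed error covariance. For the sedation arm the design is the
Kronecker product `[1, x_decile] ⊗ [state indicators]` — one intercept
and one slope per state, with the slope covariate centered at decile 1
so intercepts are decile-1 values; slopes exponentiate to odds ratios.
Σ̂ is ridged by `1e-8 · mean(diag Σ̂)` whenever its smallest eigenvalue
falls below that level, since finite-replicate bootstrap covariances can
be near-singular.

Across contrasts, `meta_summary` stacks per-contrast blocks with a
block-diagonal Σ̂ and fits a common intercept and decile slope — a
fixed-effect consolidation. Random-effect variance components are not
estimated; between-contrast heterogeneity is reported descriptively as
the SD of per-contrast slopes.

## Across-subject covariance decoding (PCA + KL)

Information can live in the across-subject covariance structure rather
than the per-voxel mean. The interest stack is column-wise z-scored and
decomposed by SVD; the retained dimensionality k comes from parallel
analysis against phase-scrambled surrogates: each map's discrete Fourier
transform keeps its amplitude spectrum but receives fresh uniform
phases (Hermitian symmetry enforced; the DC — and for even lengths the
Nyquist — coefficient is kept verbatim, so the mean and the spectrum are
preserved exactly). Surrogates therefore share each map's spatial
autocorrelation, which is the property that otherwise inflates
dimensionality estimates, while cross-subject covariance is destroyed.
k is the largest m such that the observed explained-variance ratio beats
the per-rank 95th percentile of 100 surrogate spectra at every rank
≤ m. By default scrambling operates on the flattened masked-voxel vector
(1-D DFT); a 3-D grid mode is available when volume geometry is known.

Classification: per bootstrap replicate, PCA is fit on the z-scored
training interest maps; out-of-bag interest and no-interest maps are
*independently* z-scored (their own column statistics), projected onto
the k training components, and each condition's projections are
summarized as a multivariate Gaussian (mean, covariance, ridge
`1e-8·tr(Σ)/k` when needed). The condition with the smaller
Kullback–Leibler divergence

```
D_KL = ½( tr(Σ_tr⁻¹ Σ_te) − k + (μ_tr−μ_te)ᵀ Σ_tr⁻¹ (μ_tr−μ_te) + ln(det Σ_tr / det Σ_te) )
```

from the training summary wins (1/0 per replicate); wins aggregate
through the same floor-free 0.632+ weighting into an expected
out-of-sample accuracy. A whole-mask signed-t decoder evaluated with the
univariate (k = 1) KL rule on its dot products is the reference decoder,
and the correlation between the two decoders' replicate win series is
reported. Out-of-bag draws with ≤ k subjects cannot support a k×k
covariance and are redrawn. SVD sign ambiguity is fixed by flipping each
loading so its largest-magnitude entry is positive.

## Perturbation controls

*Noise:* inside each replicate, Gaussian noise with per-voxel SD
`c·|t_v|` (c ∈ {0,…,5}; `N(0, c|t|)` is read as an SD — see Limitations)
is added to the training t-map, which is then converted to
`r = t/√(t² + df)` before binning and scoring; AUCs average over the
replicates (500 iterations at the paper-scale default). *Voxel
subsampling:* a fresh uniform subset of the requested size (defaults
100–10,735) is drawn inside each replicate before decoder construction.
*Region matching:* decoders are built from one named region at a time,
subsampled to a common voxel count inside each replicate, making
regional AUC curves comparable. c = 0 and full-size subsampling are
exact no-ops under the same seed.

## Sedation arm

With a naturalistic stimulus there is no task vector, so the *training*
subjects' average seed-region (auditory analog) timecourse stands in for
it; per-voxel betas of task and rest runs regressed on `[1, s(t)]` form
the interest/no-interest stacks, and the decile machinery applies
unchanged. The task vector, the beta maps, and the decoders are all
re-derived from the training subjects inside every bootstrap replicate,
which is what keeps the out-of-bag evaluation non-circular. The
whole-ROI variant uses one signed-t decoder per region (no deciles).

Connectivity: within-subject FC is the correlation between two regions'
mean timecourses within one subject; intersubject FC (ISFC) correlates
subject i's seed timecourse with the *other* subjects' mean target
timecourse, so only stimulus-locked shared variance survives — at rest
ISFC is zero in expectation. Estimates are Fisher-z averaged across
subjects and transformed back; |r| = 1 contributions (e.g. a region
correlated with itself) are excluded with a warning.

The state effect on ISFC is tested with a Wald-type quadratic form on
the state-mean subject-level z vectors, `n · Σ_s (m_s − m̄)ᵀ S⁻¹ (m_s −
m̄)` with S the pooled within-state covariance (≈ χ² with
pairs × (states − 1) df under the null), and a permutation null obtained
by shuffling state labels within subject; `p = (1 + #{perm ≥ obs})/(1 +
n_perm)`. The statistic is this package's construction: it matches the
degrees of freedom of the reported real-data test, but the original
statistic was not specified.

## Synthetic studies

**Map studies.** `B_NI = baseline + ε`, `B_I = baseline + δ + F Lᵀ + ε`
with a smooth shared baseline (cancels in the pairing), i.i.d. Gaussian
noise (SD 1 by default), and a per-voxel effect δ by profile:

* *widespread* — δ_v ~ N(0, effect_scale²) at every voxel, default
  effect_scale 0.3: weak relative to noise (per-voxel |t| mostly below
  conventional thresholds at n = 30) but decodable by aggregation. The
  Normal form is a modeling assumption; no empirical effect-size
  distribution is implied.
* *localized* — a contiguous block (blob_fraction·p voxels) with a
  *constant* effect: the classical coherent suprathreshold cluster. A
  Gaussian-magnitude blob would scatter weak signal voxels across the
  middle deciles and contaminate them.
* *null* — δ ≡ 0 and no latent component.

The optional latent component `F Lᵀ` (rank k, scores ~ N(0,
latent_strength²)) uses loadings smoothed by a moving average over voxel
index and scaled to unit RMS, so surrogate-based parallel analysis faces
realistic spatial autocorrelation. A subject-level motion covariate with
configurable correlation to mean map amplitude (default 0) supports the
orthogonalization control.

**Sedation studies.** A single smoothed standard-normal stimulus s(t)
(Gaussian kernel, bandwidth 3 samples — a stand-in for hemodynamic
smoothing; no HRF convolution) is shared by all subjects and states.
Subject i's task run in a state with attenuation g is

```
x_v(t) = b_i · a_v(g) · s(t) + 0.5 · c(t) + η_v(t),
a_v(g) = seed_amplitude (seed voxels) or offseed_amplitude · (1 − g),
```

with rest runs omitting the stimulus term. Defaults: 17 subjects, 150
timepoints (a 5-minute run at a 2-s sampling interval), five regions of
40 voxels (seed + posterior/anterior/visual/motor analogs) plus 200
background voxels, noise SD 1, seed amplitude 1, off-seed amplitude
0.05, states awake/light/deep/recover with g = (0, 0.4, 0.8, 0.3).

Two terms deserve explanation. `b_i ~ N(1, 0.5²)` is a per-subject
responsiveness gain: without between-subject amplitude variability,
coherent aggregation over even a handful of voxels drives across-subject
decoding to AUC = 1 in every state and the sedation ordering becomes
untestable; with it, the awake state sits around AUC 0.9 off-seed and
deep sedation near 0.6 — the dynamic range the analysis is about. The
shared within-subject component `c(t)` (one per subject-run, all voxels)
gives the regions of one subject common variance so within-subject FC is
positive and stable across states; it is generated *orthogonal* to s(t)
because intrinsic activity is modeled as stimulus-independent, and at
T = 150 a chance correlation of order 1/√T would otherwise act as a
per-subject fake stimulus amplitude comparable to the off-seed
amplitudes themselves.

What the generator does **not** emulate: hemodynamic response functions,
physiological noise spectra, realistic head-motion timeseries, spatial
smoothness of the noise, or anatomically shaped regions. Passing tests
demonstrate that the estimators are calibrated and recover known
structure under these idealized conditions; they do not certify
performance on real scanner data.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale by design:
null calibration uses 20 studies of n = 30, p = 2,000 with 100 bootstrap
replicates; widespread recovery uses p = 10,000; parallel-analysis
calibration uses 100 noise studies of 20 × 300 with 100 surrogates each;
the sedation mirror uses the generator defaults with 60 replicates per
state; nested-bootstrap and perturbation examples use reduced loop
counts. The full 500 × 100 nested bootstrap and 500-iteration
perturbations remain available through their configs.

## Numerical choices and degenerate inputs

* Zero-variance voxels: t = 0 (keeps partitions total). Constant
  columns z-score to 0. Constant timecourses are excluded from FC with a
  warning; a constant task vector is an error.
* AUC ties contribute 1/2 (standard U convention).
* R̂ is clamped to [0, 1] even when θ̂app < 0.5 < θ̂•boot.
* Covariance ridges: `1e-8 · mean(diag)` (GLS) and `1e-8 · tr(Σ)/k`
  (KL), applied only when the smallest eigenvalue is below the ridge.
* Collinear covariates in score orthogonalization fall back to a
  minimum-norm projection with a warning; collinear GLS designs raise an
  error naming the offending columns.
* All stochastic procedures take explicit seeds; replicate-indexed
  substreams make results independent of worker scheduling.

## Known limitations

* Whether `N(0, c|t|)` denotes an SD or a variance is ambiguous in the
  notation; this package reads it as an SD (the unsquared second
  argument), which the noise-injection tests pin down explicitly.
* The boundary decile next to a strong localized blob inherits signal
  through rank instability (single strong voxels slip in within
  bootstrap replicates) and genuinely decodes above chance; "null
  deciles" must therefore be defined by replicate-level membership.
* The fixed-effect `meta_summary` understates uncertainty when contrasts
  are truly heterogeneous; heterogeneity is surfaced but not modeled.
* The ISFC permutation statistic is a declared construction, not a
  reproduction of the original (unspecified) test.
* The parallel-analysis threshold (per-rank 95th percentile of the
  surrogate spectra) is a convention; "above the noise floor" admits
  alternatives (max, mean) that would shift k on borderline data.
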