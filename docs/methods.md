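# Methods

This note documents the models, conventions and design decisions behind
`cthist`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometry and preprocessing

Arrays are indexed `(z, y, x)`; spacing and origin triples are stored in
the same order as the array axes. The origin is carried through I/O but no
feature depends on it — every computation uses intensities and spacing
only.

**Resampling.** Images are resampled to an isotropic target grid (default
0.5 mm) by trilinear interpolation on voxel-center coordinates. The output
dimension per axis is `ceil(n_in * s_in / s_out)`, anchored at the input
origin, so the field of view is never cropped; coordinates beyond the last
voxel center clamp to the nearest edge value. A volume already at target
spacing reproduces itself to 1e-9. Masks follow the image onto the same
grid with nearest-neighbor interpolation (ties at half-integer coordinates
round to the higher index) and are never smoothed, so they stay strictly
binary.

**Denoising.** A Gaussian filter of variance 0.5 follows resampling. The
variance carries no published units; we interpret it in physical space
(mm², σ ≈ 0.707 mm ≈ 1.414 voxels at 0.5 mm spacing) because the filter is
applied to the resampled grid; a voxel-unit interpretation is available via
`PreprocessConfig.gaussian_units="voxel"` for sensitivity analysis. The
kernel is truncated at 4σ with reflective edges; variance 0 is the exact
identity. Order of operations is fixed: resample → denoise → extract.

## First-order features

The 42 features are functions of the multiset of HU values inside the ROI.
Conventions, chosen once and documented because first-order definitions
vary between toolkits:

* **Moments** are population (1/N) moments; kurtosis is Fisher *excess*
  kurtosis, consistent with negative reported values in this literature.
  Skewness/kurtosis of a constant ROI are NaN, serialized as empty CSV
  cells; subjects are never dropped.
* **Percentiles/quantiles** interpolate the sorted sample linearly at
  position (N−1)q (numpy's default). The ladder satisfies, by
  construction, quantile 0.25 = percentile 25, quantile 0.5 = median,
  quantile 0.75 = percentile 75.
* **`frequency_size` ≡ `volume_count` − 1** is reproduced as a feature-
  toolkit convention, not a principled statistic.
* **Histogram features** use equal-width bins spanning [min, max]:
  256 bins for entropy (−Σ p log₂ p) and energy (Σ p²), 16 bins for
  uniformity (Σ p²). Two bin counts are used because reported uniformity
  (~0.5) and energy (~0.01) magnitudes for the same ROIs are impossible
  under a single binning; both counts are configurable. A constant ROI
  occupies one bin: entropy 0, energy = uniformity = 1.
* **`mean_deviation`** = (1/N)Σ|xᵢ − mean| and **`relative_deviation`** =
  N·mean_deviation/mean are explicit house definitions: no published
  definition exists for these two names (reported medians for them are
  even negative, inconsistent with any absolute-deviation formula), so
  numeric parity with published per-patient values is not claimed and the
  definitions must not be tuned toward them.

Every feature is verified against an independent brute-force oracle
(explicit loops over the sorted sample) on random ROIs, to 1e-9 relative.

## Shape features

Volume is voxel count × voxel volume. Surface area has two backends:

* **mesh** (default): marching cubes at iso-level 0.5 after a fixed
  0.8-voxel Gaussian anti-aliasing of the binary mask. Raw binary marching
  cubes produces 45° staircase facets that overstate the area of smooth
  bodies by ~9%; the sub-voxel smooth lets the iso-surface interpolate
  through voxel corners and lands within ~0.5% of the analytic area for
  digitized balls with r ≥ 10 voxels (measured across r = 5–15 mm at
  0.5–1 mm spacing). Single-voxel masks fall back to their six faces.
* **voxel-face**: the sum of exposed voxel faces, exact for axis-aligned
  bodies and used wherever closed-form oracle values exist (a 1 mm cube at
  0.5 mm spacing has V = 1 mm³, A = 6 mm², sphericity
  π^{1/3}·6^{2/3}/6 ≈ 0.80600).

Sphericity, compactness1/2 and spherical disproportion are the standard
dimensionless ratios and satisfy sphericity = compactness2^{1/3} =
1/spherical_disproportion identically. The maximum 3-D diameter is the
largest pairwise distance between surface-voxel centers; restricting to
surface voxels (and, above 2000 points, to convex-hull vertices) provably
preserves the maximum, and equality with the all-pairs search is tested on
small masks.

## Two-step feature selection

Step 1 routes each feature to its group test: Student's t if Shapiro–Wilk
(per group, as specified) and Bartlett all exceed α = 0.05, otherwise
Mann–Whitney U (exact when n₁+n₂ ≤ 20 without ties, else the normal
approximation with tie correction). Survivors are confirmed by a
single-feature logistic regression on the standardized feature (Wald test;
standardization is for numerical stability — the Wald p is invariant to
affine rescaling). Complete separation is detected up front and handled by
a ridge-stabilized Newton fit (L2 penalty λ = 1 on the slope), flagged in
the report.

Step 2 computes the Spearman matrix of the survivors and greedily resolves
every pair with |ρ| > 0.9, strongest correlation first, dropping the
feature with the **larger** logistic p (exact ties drop the later feature
in the canonical 42-name order). The drop rule is not standardized
anywhere, so it is fixed, deterministic and logged (`eliminated_by`);
the resulting representative set is pairwise |ρ| ≤ 0.9 by construction.

Calibration of the screen is verified by simulation: under the null the
per-feature step-1 and logit rejection rates sit at the nominal 5% level
(acceptance band 3–7%).

## ROC and DeLong

AUC is the Mann–Whitney pair-counting estimator (ties ½), verified against
brute-force pair enumeration on every test set. Curves sweep the unique
scores descending (predict positive at score ≥ t). The operating point
maximizes Youden's J with ties resolved to the lower threshold — the
criterion used for reported thresholds is not named in this literature, so
Youden is the package's documented choice. Score models are logistic fits
(probability scale), with duplicate columns collapsed and a ridge fallback
under separation.

Variance and CIs use DeLong's structural components: with per-positive
components V₁₀ and per-negative V₀₁, var(AUC) = S₁₀/m + S₀₁/n, CI =
AUC ± 1.96·SE truncated to [0, 1]; paired comparisons use the analogous
covariance of component differences. Measured properties (recomputed by
the suite and acceptance script): the variance at n = 200 is within 15% of
a 2000-resample bootstrap, and the 95% CI covers a true AUC of 0.75 in
≈ 93.5% of simulated 33 + 24 cohorts — real but slightly anti-conservative
Wald coverage at this sample size, inside the accepted 93–97% band though
near its lower edge (hence the coverage test uses 10,000 replicates, so
Monte-Carlo error is small against the band).

Demographics use a pooled two-sided t-test for continuous variables and
the **uncorrected** Pearson chi-square (df = 1) for 2×2 tables; the
uncorrected statistic is the one that reproduces the published p-values
(smoking p = 0.001, gender p = 0.112) exactly, and Yates' correction
remains available. The published age p-value (0.104) is not reproducible
from the published group means/SDs under any standard t-test (both pooled
and Welch give p ≈ 0.56); it is treated as a probable inconsistency in the
source table, not a target.

## Synthetic data

**Image path.** Each subject is an ellipsoidal lesion (semi-axes within
±25% of a radius drawn from 5–10 mm) embedded in Gaussian background noise
(40 ± 20 HU, soft-tissue-like), on an anisotropic acquisition grid drawn
from {1.0×0.717×0.717, 0.625×0.488×0.488, 0.8×0.6×0.6} mm. Lesion voxels
follow group-conditional models: EGFR(+) draws from a wide bimodal normal
mixture (0.55·N(150, 180²) + 0.45·N(750, 200²), spanning ≈ −60 to 1100 HU,
hence large range and 97.5% quantile); EGFR(−) from a lognormal with
median 100 HU and σ_log = 0.7 (long right tail, hence large skewness,
97.5% quantile ≈ 395 HU). `effect_scale` mixes each subject's voxels
between the own-group and other-group model with weight (1 ± s)/2, so
s = 0 makes the groups identically distributed and s = 1 fully separated.
Everything is deterministic in (seed, subject index).

**Fast path.** For selection/ROC stress tests at scale, 42-dimensional
feature vectors are drawn directly from a three-factor latent model. The
factors *are* the planted features (range, skewness, quantile 0.975), with
pairwise correlations (0.35, 0.75, 0.35) — range and the upper quantile
genuinely co-vary in intensity data — and standardized group shifts
(1.2, −1.0, 1.1)·effect_scale; the skewness shift is negative, pointing
toward the EGFR(−) group. Each of the other 39 features is an attenuated
noisy copy of one factor: within-group correlation 0.997 with its parent
and a group shift attenuated by a fixed 0.3–0.7 grid. This makes every
block internally redundant (|ρ| > 0.9) while guaranteeing the parent
dominates each member both in correlation and in univariate significance.
Effect sizes and correlations were fixed once by an a-priori power
analysis targeting clear group separation (per-factor z ≈ 3.7–4.5) at the
33 + 24 design, and are not tuned thereafter.

The fast path is a statistical fixture: its marginals do **not** satisfy
the arithmetic identities of genuinely extracted features (range =
max − min etc.), which are tested on the extraction path. What passing
tests show is that the procedure recovers a known sparse signal under
realistic redundancy and stays calibrated under the null — not that any
specific clinical effect size is reproduced; neither generator emulates
real bone texture, CT physics, or inter-scanner variation.

## Problem sizes

Simulation scales are chosen to keep the default suite fast while leaving
Monte-Carlo error small against each acceptance band: 1000 replicates for
type-I-error rates, 2000 bootstrap resamples for the DeLong variance
check, 10,000 cohorts for CI coverage (500 in the acceptance script's
summary figure), 100 seeds for planted recovery and null-emptiness, 100
random ROIs for oracle equivalence, and cohorts of 57 (33 + 24) subjects
throughout, matching the study design the defaults encode. Direction-of-
effect checks on the image path use 60–200 small-radius subjects.

## Known limitations

* Exact numeric parity with any proprietary feature toolkit is not
  claimed: histogram binning, percentile conventions and the surface
  algorithm of such toolkits are unpublished. The conventions here are
  explicit and configurable instead.
* DeLong Wald CIs are mildly anti-conservative at n ≈ 57 (coverage
  ≈ 93.5%, not 95%); a logit-transformed interval would improve this but
  is not the reported form.
* The mask is resampled by nearest neighbor; partial-volume weighting at
  lesion boundaries is not modelled.
* The ridge fallback under separation yields finite but shrinkage-biased
  slopes; its p-values are flagged rather than treated as exact.
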