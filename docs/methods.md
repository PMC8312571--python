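# Methods

This note documents the models, numerical choices and limitations of
`wmhtex`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis in one paragraph

The working hypothesis is that cerebral small vessel disease alters brain
parenchyma beyond the visibly lesioned white matter. The package therefore
quantifies the *texture* of normal-appearing brain on axial T2-FLAIR,
asks how much of the WMH burden that texture predicts (ElasticNet under
repeated nested cross-validation), distills a stable radiomic signature,
and relates the signature to cardiovascular phenotypes through canonical
correlation analysis with permutation inference.

## Masking and the outcome

The extraction region is brain − ventricles − WMH, followed by a
morphological opening with a 3×3 all-ones kernel applied **per axial
slice**. With ~6 mm slices a 3×3×3 kernel would erode whole slabs of a
one-slice-thick structure, so the planar reading of "3×3" is the only
geometrically sensible one. The opening is applied to the final subtracted
mask (not to its inputs).

The outcome is the WMH/brain *voxel-count ratio*, Box-Cox transformed:
`y = (x^λ − 1)/λ` (λ ≠ 0), `y = ln x` (λ = 0). λ is fitted once per cohort
by profile maximum likelihood, bracketed in [−3, 3] (tolerance ~1e−4 via
Brent refinement). Ratios are kept as fractions internally; a percentage
scaling only shifts the transform by a deterministic monotone map.
Zero-lesion subjects would make the transform undefined, so when zeros are
present all values are shifted by half the smallest positive fraction; the
shift and λ are stored with every burden record.

## Radiomics

All texture is computed **in-plane**: neighbourhoods, runs, zones and
filters act within axial slices, and raw counts are merged over slices
(and, for GLCM/GLRLM, over the four in-plane directions) before feature
formulas are applied. Merging counts — rather than averaging per-direction
features — is what makes the features exactly invariant to in-plane 90°
rotations and flips, a property the test suite asserts directly.

Pipeline per subject: resample to 1×1×6 mm (linear for intensities,
nearest-neighbour for masks, physical extent preserved to one voxel) →
z-score intensities against the in-mask mean/SD and rescale by 100 →
discretize with fixed bin width 5 → features. The normalization scale
matters: fixed bin width 5 on raw scanner units is arbitrary across
cohorts, whereas after scaling one bin is 0.05 in-mask SD.
Discretization is `level(x) = floor(x/w) − floor(min/w) + 1`, levels
starting at 1.

Filters: per-slice Laplacian of Gaussian with σ given in mm (converted to
voxels by the in-plane spacing, kernel truncated at 4σ, and DC-corrected so
a constant image maps exactly to zero); an undecimated single-level coif1
wavelet decomposition implemented as separable convolution with the
decomposition filters (keeps sub-band images on the mask grid; band `LH`
means low-pass along axis 0, high-pass along axis 1); and rotation-invariant
uniform local binary patterns (radius 1, 8 neighbours) whose code image is
then discretized with the same bin-width rule.

Texture families use the standardized formula sets (e.g. GLRLM
ShortRunLowGrayLevelEmphasis = (1/N_r) Σ P(i,j)/(i²j²)). Conventions worth
recording: the GLCM is symmetrized; GLSZM zones are 8-connected in-plane;
the GLDM dependence index counts the centre voxel plus neighbours within
gray-level tolerance α = 0 (so j runs 1..9 in 2D); NGTDM excludes voxels
with no in-mask neighbour. Every family is validated against an
independent brute-force enumeration on hundreds of random small volumes.

Shape descriptors come from a triangular mesh extracted at the 0.5
iso-level of the padded, lightly smoothed (σ = 1 voxel) mask — a raw
staircase mesh overestimates the surface of smooth objects by ~8%, which
would bias Sphericity = (36πV²)^{1/3}/A well below 1 for a perfect ball.
Axis lengths are 4·√eigenvalues of the physical voxel-coordinate
covariance; Maximum2DDiameter{Slice,Column,Row} are the largest pairwise
mesh-vertex distances in the axial/coronal/sagittal projections (convex
hull first, for speed). First-order percentiles use linear interpolation.

The emitted feature count is configuration-dependent (the default filter
set yields ~842 named features per subject plus shape); the feature
dictionary JSON records filter/class/feature for every column.

## Burden prediction and the signature

Per repetition r (seed = base + r): subjects are split into five folds
stratified on the continuous outcome by decile bins (quantile-bin, shuffle
within bin, deal round-robin — fold sizes differ by at most one). **One**
fold of size ⌈n/5⌉ is held out; at n = 4,163 and 30 repetitions this yields
exactly 30 × 833 = 24,990 out-of-sample predictions, which is the split
accounting the scheme is designed to reproduce (a full five-fold outer
rotation is available via `outer_mode="rotate"`). On the outer training
set, predictors are standardized (training statistics only — a leakage test
asserts held-out rows never contribute) and ElasticNet hyperparameters are
chosen by inner five-fold CV over l1-ratio ∈ {0.1, 0.5, 0.7, 0.9, 0.95, 1.0}
and a 50-point auto-scaled penalty path, minimizing mean squared error.
"Selected" features are those with exactly nonzero coordinate-descent
coefficients in the outer refit (ℓ1 solutions are exactly sparse; no
epsilon). The radiomic signature is the intersection of the 30 selected
sets, with selection frequencies reported for every ever-selected feature.

`predict` on new data uses a final full-data refit at the median chosen
hyperparameters; it is a convenience, not part of the evaluation protocol.

Ancillary analyses: leave-one-site-out CV (train on all sites but one,
inner CV as above) and residual-by-group diagnostics (pooled out-of-sample
residual per ordinal group, e.g. stroke-severity score, with a Spearman
trend statistic).

## CCA and inference

Classical CCA via SVD of the whitened cross-covariance
Σ_xx^{−1/2} Σ_xy Σ_yy^{−1/2}; rank-deficient covariance blocks raise an
error with a rank report (the pipeline pre-selects a numerically
independent signature subset by pivoted QR when a small cohort makes
features collinear). Continuous variables whose Shapiro–Wilk test (on a
seeded subsample of ≤ 5,000, the implementation bound) rejects normality at
α = 0.05 get a rank-based inverse-normal transform; binaries enter as 0/1
untransformed, since a normality test is meaningless for them.

Function k is tested parametrically through Λ_k = Π_{i≥k}(1 − r_i²) with
Rao's F approximation (the exact Pearson F test at p = q = 1, asserted to
1e−8), and nonparametrically by permutation with Λ_k as the statistic
(smaller = stronger). For k = 1 the rows of whitened Y are permuted
directly. For k ≥ 2 the default scheme first projects the leading k−1
canonical variates out of both sets and permutes the residualized data
(sequential removal). The naive alternative — re-fitting the full CCA on
permuted data and reading off Λ_k — is available via
`higher_order="naive"`, but it is **anti-conservative** whenever stronger
functions carry real association: the observed k-th correlation lives in
the residual space left by the true signal while the permuted one is a
k-th order statistic of a full null spectrum. In a planted two-factor
design (ρ = 0.8, 0.4) the naive test declares three or more functions
significant in roughly half the replicates, whereas the residualized
default recovers exactly two; this motivated making sequential removal the
default. Permutation p-values use the add-one estimator
(1 + #{Λ_perm ≤ Λ_obs})/(1 + n_perm); Benjamini–Hochberg is applied across
the s = min(p, q) functions.

Loadings are Pearson correlations between each variable and its own set's
variate. The scree "explained variance" is reported under both common
conventions — r_k²/Σr_j² and the mean squared loading per function —
because the quantity is not uniquely defined in the literature.

## Synthetic cohort

The generator's defaults encode the study-population description: age from
a truncated normal (mean 62.8, SD 15.0, bounds [18, 100] — an adult stroke
cohort cannot contain impossible ages; truncation biases the realized mean
down by ~0.2 y), binary risk factors Bernoulli at the published prevalences
(female 0.420, HTN 0.679, DM 0.165, AF 0.143, CAD 0.185, smoking 0.320),
and WMH volume lognormal with location ln 4.2 and scale
σ_log = ln(11.2/1.4)/(2·Φ⁻¹(0.75)) ≈ 1.5415, i.e. the distribution whose
median and quartiles equal the published 4.2 (1.4–11.2) mL. Covariates act
on the **log** scale (the same skewness that motivates the Box-Cox
outcome): log WMH = μ + Σ coef_j·z_j + σ·ε with standardized covariates, so
σ_log is the residual scale and the zero-coefficient default reproduces the
marginal exactly. Brain volume is normal (1400 ± 130 mL, configurable) —
no published distribution exists for it, so this is a documented choice.
Stroke-severity scores are a rounded lognormal with median 3, missing at
the published 46.3% rate; optional MCAR missingness on binaries exercises
median imputation (rows missing age or sex are dropped, mirroring the
exclusion rule; a binary median tie at 0.5 resolves to the mode).

Image phantoms are geometric, not anatomical: brain = rasterized ellipsoid,
ventricles = central ellipsoid pair, lesions = the requested number of
voxels chosen by a periventricular propensity field (distance decay from
the ventricles plus smooth seeded noise), so lesion volume matches the
request to voxel rounding. Default grid 96×96×24 at 1×1×6 mm — the
extraction grid, at desk scale. Covariates modulate texture two ways:
global noise-SD scaling and smooth random patches added inside the brain
(amplitudes per covariate, squashed through tanh). This produces
filter-detectable heterogeneity *analogous to* "older brains look more
heterogeneous", with no claim of biological realism: passing tests
demonstrate that the machinery recovers planted structure, not that real
FLAIR texture behaves this way. Per-site effects beyond an intensity
offset, scanner artifacts, and anatomically realistic lesion shapes are
out of scope. When a drawn lesion volume exceeds what a desk-scale phantom
can host, the pipeline clips it to ~30% of the phantom brain volume and
logs the clip.

`generate_feature_table` plants exact population structure for
recovery tests: each planted canonical pair m has latents
z_y = ρ_m z_x + √(1−ρ_m²)ξ, and one column per set carries its latent
verbatim, so the population m-th canonical correlation is exactly ρ_m;
burden is X·β_true + noise with a known sparse β_true.

## Problem sizes and test conditions

The repository exercises the machinery at desk scale: split accounting at
the full n = 4,163; cohort calibration at n = 4,163; texture-matrix
equivalence on 200+ random volumes ≤ 8×8×3 with ≤ 5 levels; permutation
type-I error over 500 null replicates (n = 300, p = 10, q = 7, 199
permutations per test); canonical-correlation recovery at n = 5,000;
sparse-support recovery at n = 1,000, p = 300, 10 informative features with
residual noise chosen for a planted out-of-sample R² near 0.93 (the
"high signal-to-noise" condition); and a 60-phantom end-to-end demo with
two filters and five repetitions. The headline numbers of the motivating
clinical analysis (R² = 0.855 ± 0.011, 68 signature features, canonical
correlations 0.81…0.15) belong to a private 4,163-subject imaging cohort
and are not reproducible from synthetic data; what the suite verifies is
that every algorithmic component is correct, calibrated, and recovers
planted truth.

## Known limitations

- 2D/in-plane texture only; a 3D mode is deliberately absent given ~6 mm
  slices.
- Fixed-bin-*count* quantization, GPU paths and alternative learners are
  not implemented.
- The phantom is geometric; conclusions about real FLAIR texture require
  real data.
- `Sphericity` can exceed 1 by up to mesh tolerance (~0.01) on voxel-scale
  regions.
- The Shapiro–Wilk gate uses a subsample above 5,000 values, so the
  transform decision is itself slightly stochastic (seeded).
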