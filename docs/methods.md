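# Methods

## Signal model

Every simulated voxel follows the isotropic (trace-weighted) diffusion
kurtosis representation

    S(b) = S0 · exp(−b·D + b²·D²·K/6)

with baseline signal `S0` (arbitrary units, default 1000), diffusivity `D`
(mm²/s) and excess kurtosis `K` (unitless, 0 = Gaussian). The quadratic
term makes the log-signal convex in `b`, so a monoexponential (ADC) fit of
the same data always understates `D`; this ADC < D ordering is a model
property and is enforced by test. The acquisition emulated is five
b-values (0, 500, 1000, 1500, 2000 s/mm²) on a 64×64 matrix with 4 slices.

The exponent is only monotone decreasing over the acquired range when
`K < 3/(b_max·D)`; voxel draws violating this (which would make the signal
rise again at high b) are redrawn and, failing that, capped just below the
limit. For the default parameter ranges this is a rare tail event.

## Synthetic cohort generator

The generator emulates a two-arm xenograft study: a control tumor line and
an EMT-induced line, 10 animals per arm.

**Tumor level.** Each tumor's (D, K, cellularity, Ki-67, E-cadherin) tuple
is drawn from a Gaussian copula with Gaussian marginals — for Gaussian
marginals this is simply a multivariate normal, so the latent correlation
matrix is also the Pearson correlation of the output. Group marginals
(defaults):

| quantity | control | EMT | units |
|---|---|---|---|
| D | 0.54 ± 0.06 | 0.46 ± 0.02 | 10⁻³ mm²/s |
| K | 1.22 ± 0.14 | 1.53 ± 0.13 | — |
| cellularity | 488 ± 42 | 700 ± 43 | cells/field |
| Ki-67 | 30 ± 8 | 55 ± 10 | % |
| E-cadherin | 70 ± 10 | 40 ± 10 | score 0–100 |

The D/K/cellularity marginals are the observed group summaries of this
tumor model. Ki-67 and E-cadherin are not numerically constrained beyond
their direction (EMT: higher Ki-67, lower E-cadherin), so their scales are
placeholders and deliberately configuration-exposed.

The correlation matrix couples the diffusion parameters to histology with
the observed pooled associations (K–cellularity +0.74, D–cellularity
−0.56, K–Ki-67 +0.73, D–Ki-67 −0.59, D–E-cadherin +0.51, K–E-cadherin
−0.59). The entries no study reports — D–K and the histology–histology
pairs — are set to plausible values (−0.6; +0.6, −0.5, −0.5) chosen once
for positive-definiteness and sign consistency. Any user-supplied matrix
is projected to the nearest positive-definite correlation matrix
(eigenvalue clipping with unit-diagonal rescale) before sampling. Draws
are truncated to physical ranges (D > 10⁻⁵ mm²/s, K ∈ [0, 3], percent
scores to [0, 100]); the group means sit several SDs inside every bound,
so truncation bias is far below Monte-Carlo resolution.

A consequence of making ADC a pure functional of (D, K): the simulated
ADC distributions are tighter than the empirically reported ones (the
in-model binormal ADC AUC is ≈ 0.93, whereas an empirical study reported
0.82 with binormal structure ≈ 0.86). Real ADC measurements carry
independent error this generator does not model; analyses of ADC's
relative performance should read the population ordering (kurtosis > ADC
here by a small margin), not the empirical small-sample value.

**Voxel level.** Within a tumor, D and K vary around the tumor means with
a coefficient of variation of 0.05 (default, configurable). Within-tumor
spread is not reported for this tumor model; 0.05 keeps ROI means faithful
to the tumor-level draw while giving the parametric maps visible texture.
The tumor ROI is an axis-aligned ellipsoid centered in the grid, with
in-plane semi-axes drawn so the center slice contains 57–214 voxels (the
ROI size range the measurement protocol assumes).

**Noise.** Magnitude (Rician) noise: S ↦ √((S+ε₁)² + ε₂²) with ε
zero-mean Gaussians of SD σ. The acquisition's SNR is unreported; the
default σ = S0/40 (b0 SNR 40, plausible for small-animal 3 T with surface
coils) is configurable and a noiseless mode exists for exact-recovery
tests. Note the goodness-of-fit implication: with 5 points and 3
parameters, E[SS_res] ≈ 2σ², so a mean kurtosis-fit R² of 0.999 — the
level reported in vivo — requires an effective b0 SNR of roughly 100
(consistent with 6 signal averages); at SNR 40 the expected mean R² is
≈ 0.994. The R² ≥ 0.999 regression check therefore runs noise-free.

**Seeding.** A master `SeedSequence` is spawned into per-stage and
per-tumor streams, so a fixed seed reproduces the cohort byte-for-byte
and resizing one group never reshuffles the other's tumors.

Not modeled (out of scope by design): anatomical (T2-weighted) contrast,
coil sensitivity, EPI distortion, motion, partial volume, and
cystic/necrotic sub-regions (measurement ROIs deliberately avoid them in
practice). Passing tests therefore demonstrate correctness of the
estimators and statistics under the stated generative model, not
robustness to those real-data artifacts.

## Voxel-wise fitting

* **ADC**: ordinary least squares of ln S on b (slope = −ADC), the
  standard monoexponential estimator; a nonlinear signal-domain variant is
  available by option, and the fit can be restricted to a b-value subset.
  All five b-values are used by default.
* **Kurtosis**: Levenberg–Marquardt minimisation of the signal-domain
  residual (MINPACK via lmfit, bounds handled by parameter transform),
  initialised from the quadratic cumulant fit of ln S on (b, b²).
  Constraints: D ∈ (10⁻⁶, 10⁻²) mm²/s; K ∈ [0, 3] — negative excess
  kurtosis is non-physical for restricted diffusion and the cap stops
  runaway estimates at high noise. Convergence: relative parameter/cost
  change below 10⁻⁸ or the evaluation cap (500 iterations' worth);
  non-convergence is flagged on the result and such voxels are excluded
  from ROI means (the excluded fraction is logged). The returned estimate
  never has a higher residual sum of squares than its initialisation.
* **R²** is always computed against the observed signal (not log-signal)
  over the fitted b-points: 1 − SS_res/SS_tot.
* No Rician-bias correction is applied (matching common practice for this
  pipeline); an optional noise-floor b-point exclusion exists and is off
  by default. At the default SNR this leaves a small downward bias in
  ROI-mean kurtosis (visible in the worked example), because the bounded
  5-point fit responds asymmetrically to noise.
* **Trace-weighted vs per-direction kurtosis**: `fit_dki_directional`
  exposes both estimators — average of three per-direction K fits versus a
  single fit of the geometric-mean (trace-weighted) signal — and reports
  their discrepancy, which is nonzero under anisotropy and bounded by
  ~60% in the configured test cases.

## ROI measurement and observer model

Measurements are taken on each tumor's center slice (maximal in-mask
area; ties break to the lower slice index) as the mean over in-mask,
converged voxels. Observer variability is modeled as ROI-placement
perturbation, not value noise: each of the 2 observers × 2 repeats gets
the true mask eroded by a random radius (default ≤ 1 voxel) and translated
in-plane (default ≤ 1 voxel), always intersected back with the true tumor
extent. The per-tumor consensus value is the arithmetic mean of the four
measurements (order-invariant). Zero jitter collapses all four
measurements and drives every ICC to exactly 1 — the pipeline identity
used as a regression anchor.

## Statistics

* **Group comparison**: two-sided pooled-variance Student t-test (Welch by
  flag); accepts raw samples or (mean, SD, n) summaries.
* **ROC**: empirical (Mann–Whitney) AUC with half-credit ties; threshold
  by exhaustive Youden-index scan over observed values (ties → higher
  sensitivity, then lower threshold); sensitivity/specificity CIs exact
  Clopper–Pearson; AUC variance and AUC = 0.5 test by DeLong placement
  values, with the 95% CI on the logit scale. Lower values call the EMT
  class positive for ADC/diffusivity; higher values for kurtosis.
* **Paired AUC comparison**: DeLong covariance of placement values,
  two-sided z-test, significance at α = 0.0167 for the three pairwise
  marker comparisons (0.05/3). Verified against R's pROC to 6 decimals.
* **ICC**: two-way random-effects, absolute agreement, single measurement
  (ICC(2,1)) by default — the "agreement" language of inter-observer
  analyses — with all standard McGraw–Wong variants selectable; computed
  via pingouin with F-based 95% CIs; bands: excellent > 0.8, substantial
  0.6–0.79. Exactly duplicated columns short-circuit to ICC = 1.
* **Correlations**: Pearson for cellularity, Spearman for the
  immunohistochemical scores (average ranks on ties), with the
  conventional |r| categories (≤ 0.24 little/none, 0.25–0.49 fair,
  0.5–0.74 moderate/good, 0.75–1.0 good/excellent).
* **qPCR utility**: fold change = 2^(−ΔΔCt).

No multiple-testing correction is applied beyond the α = 0.0167 rule for
the AUC comparisons.

## Problem sizes and numerical choices

The test suite and the reproduction script run at desk scale: binormal
AUC checks use 10⁵ draws per group (Monte-Carlo SE < 0.001), copula
correlation checks 10⁴ tumors (SE ≈ 0.005), cohort-moment checks 10⁴
draws with 3-SE tolerances, the DeLong null calibration 1000 simulated
datasets of 25 + 25, and pipeline-level tests a 32×32×3 grid with 3 + 3
tumors; the full-grid goodness-of-fit check fits one 64×64×4 tumor.
Grid-search oracles for the LM fitter use two-stage dense grids; exact
ties in the oracle break to the lexicographically lowest (D, K).

## Known limitations

* Small-sample empirical quantities (n = 10 per arm) — a specific ROC
  threshold, sensitivity/specificity, a single study's ADC AUC or ICC
  values — vary strongly between realizations and are checked only by
  direction and band, never by point value.
* The kurtosis ROI means are biased low at the default SNR (see fitting
  notes); group discrimination is essentially unaffected because the bias
  is shared between arms.
* The copula reproduces pairwise correlations only; higher-order joint
  structure of parameters and histology is not constrained.
* Only the isotropic trace-weighted signal is simulated; the directional
  estimator comparison uses constructed per-direction signals, not a full
  kurtosis tensor.
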