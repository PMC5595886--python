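# dkisim

Simulation and analysis of diffusion-kurtosis MRI (DKI) in two-group tumor
xenograft studies.

## The problem

Epithelial–mesenchymal transition (EMT) makes carcinoma cells more
migratory and invasive, and it changes tumor microstructure: higher
cellularity, more heterogeneity, higher Ki-67 proliferation, lower
E-cadherin adhesion. Diffusion MRI can probe this non-invasively. The
conventional apparent diffusion coefficient (ADC) assumes Gaussian
diffusion; in dense, heterogeneous tissue diffusion is non-Gaussian, and
diffusion kurtosis imaging captures the deviation:

```
kurtosis model:        S(b) = S0 · exp(−b·D + b²·D²·K/6)
monoexponential model: S(b) = S0 · exp(−b·ADC)
```

where `b` is the diffusion weighting (s/mm²), `D` the kurtosis-corrected
diffusivity (mm²/s), and `K` the unitless excess kurtosis (`K = 0` is
perfectly Gaussian diffusion). EMT-induced tumors show lower `D` and
higher `K` than controls, and `K` correlates positively with cellularity
and Ki-67, negatively with E-cadherin.

This package is for researchers who want a fully synthetic, seeded,
end-to-end testbed for that analysis: it simulates two-group multi-b-value
DWI cohorts with known ground truth and correlated histology covariates,
fits ADC and (D, K) maps voxel-by-voxel, summarises them over
observer-perturbed ROIs, and computes the group-discrimination and
agreement statistics (Student t-tests, ROC with Youden thresholds, DeLong
AUC comparison at α = 0.0167, two-way ICCs, Pearson/Spearman correlations).

## Worked example

The analysis is a sequence of four drivers (each is a thin script over the
`dkisim` library; a `dkisim` CLI with `simulate`/`fit`/`roi`/`stats`/
`run-all` subcommands wraps the same stages):

```bash
python analysis/01_simulate_cohort.py  --seed 1 --out results/cohort
python analysis/02_fit_parameter_maps.py --cohort results/cohort --out results/maps
python analysis/03_measure_rois.py     --cohort results/cohort --maps results/maps \
                                       --out results/measurements.csv --seed 1
python analysis/04_group_statistics.py --measurements results/measurements.csv \
                                       --cohort results/cohort --out results/report.json
```

With seed 1 the simulated cohort is 10 control + 10 EMT tumors
(64×64×4 grid, b = 0/500/1000/1500/2000 s/mm², Rician noise at b0
SNR 40), and the final stage prints:

```
group comparison (x10-3 mm2/s for ADC/D):
  adc          control 0.421±0.039  emt 0.350±0.011  p=0.0000
  diffusivity  control 0.530±0.047  emt 0.458±0.019  p=0.0003
  kurtosis     control 1.054±0.123  emt 1.368±0.113  p=0.0000
ROC:
  adc          AUC 1.00 (1.00-1.00)  threshold 0.363 (less)  sens 100%  spec 100%
  diffusivity  AUC 0.97 (0.81-1.00)  threshold 0.484 (less)  sens 100%  spec 80%
  kurtosis     AUC 0.98 (0.82-1.00)  threshold 1.152 (greater)  sens 100%  spec 90%
DeLong AUC comparisons (alpha 0.0167):
  adc_vs_diffusivity       dAUC +0.030  p=0.320
  adc_vs_kurtosis          dAUC +0.020  p=0.405
  diffusivity_vs_kurtosis  dAUC -0.010  p=0.811
kurtosis-cellularity: r=0.82
```

Reading this: the EMT group has lower fitted diffusivity (0.458 vs 0.530
×10⁻³ mm²/s) and higher kurtosis (1.37 vs 1.05), both strongly significant
at n = 10 per group; each parameter's ROC threshold is the Youden-optimal
cutpoint (e.g. diffusivity ≤ 0.484 ×10⁻³ mm²/s calls a tumor EMT); none of
the three pairwise AUC differences reaches the α = 0.0167 DeLong
significance level at this sample size; and kurtosis correlates strongly
and positively with the simulated tumor cellularity. Noisy voxel-wise
fits shrink the ROI-mean kurtosis below its ground-truth group means
(1.22/1.53) — a real bias of 5-point kurtosis fitting at finite SNR, see
`docs/methods.md`.

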