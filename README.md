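# petadc

Correlation analysis of PET standardized uptake values (SUV) and MR
apparent diffusion coefficients (ADC) in prostate cancer lesions, built
around a seeded digital phantom cohort with known ground truth.

## The problem

Simultaneous PET/MR imaging of prostate cancer yields two quantitative
lesion read-outs that are expected to move in opposite directions:
Ga-68 PSMA uptake (SUV) rises with tumor burden while water diffusivity
(ADC) falls with cellularity. Whether — and how strongly — lesion-level
histogram features of the two maps are rank-correlated, and how much the
choice of PET attenuation-correction (AC) method distorts the SUV
features, are questions a cohort analysis must answer with small n and
noisy maps. This package implements that analysis as a tested pipeline:

1. **Quantitation** — ADC maps from two-b-value DWI via the
   mono-exponential model `S(b) = S0 · exp(−b·ADC)` (b = 0 and
   800 s/mm², ADC reported in 10⁻³ mm²/s), and body-weight SUV maps
   `SUV = C[Bq/mL] · W[g] / A[Bq]` with half-life decay correction
   (T½ = 4057.7 s for Ga-68).
2. **Masking** — lesion ROI series by percentage-of-SUVmax thresholding
   (10…60%), nested and derived from the reference PET.
3. **Features** — six first-order histogram statistics per lesion and
   modality: mean, max, min, median, excess (Fisher) kurtosis, skewness
   (population moments, divisor n).
4. **Analysis** — 6×6 Spearman grids (ADC features × SUV features)
   across the cohort with exact small-n p-values, and AC-method error
   quantification via the average relative absolute error
   `avg.RAE = (1/N) Σ |Pₓ − P_ref| / P_ref · 100`, compared between
   methods with paired t and Mann–Whitney–Wilcoxon tests.
5. **Phantom** — a nested-ellipsoid synthetic cohort (27 subjects,
   17 peripheral-zone / 10 transitional-zone lesions by default) whose
   lesion-level (ADC_mean, SUV_mean) pairs come from a Gaussian copula
   with a programmable rank correlation, with Rician DWI noise and
   per-method multiplicative PET bias fields — so every downstream
   stage has a recoverable ground truth.

## Worked example

```python
import petadc as pa

spec = pa.PhantomSpec(coupling_rho=-0.5)          # programmed Spearman rho
cohort = pa.generate_cohort(spec, n_subjects=27, n_pz=17, seed=1)

table = pa.cohort_feature_table(cohort, "CT_reference", 60)
grid = pa.correlation_grid(table, "CT_reference", 60)
print("rho(ADC_mean, SUV_mean) =", round(grid.rho[0, 0], 3),
      " p =", round(grid.p_values[0, 0], 4))

report = pa.feature_error_report(cohort)
print(report.table[["MRI_like_mean", "DL_like_mean", "t_test_p"]].round(2))
```

prints

```
rho(ADC_mean, SUV_mean) = -0.663  p = 0.0002
          MRI_like_mean  DL_like_mean  t_test_p
feature
mean               2.58          1.63      0.02
max                5.20          3.04      0.01
min                4.74          1.84      0.00
median             2.79          1.96      0.11
kurtosis          29.96         11.41      0.00
skewness          43.06         26.34      0.04
```

The recovered rank correlation is negative and significant, consistent
with the programmed inverse coupling of −0.5 (a single 27-subject cohort
scatters around it with sd ≈ 0.14). The error table shows the expected
AC pattern: the lower-amplitude, deep-learning-like bias model produces
roughly half the SUV error of the MRI-like model on every feature, and
the histogram **shape** statistics (kurtosis, skewness) are an order of
magnitude more sensitive to AC bias than the location statistics.

A command-line interface mirrors the library:

```bash
petadc simulate --seed 1 --out cohort/          # write NIfTI cohort + manifest
petadc run --seed 1 --out results/              # full analysis
petadc correlate --manifest cohort/manifest.csv --threshold 60 --out corr.csv
petadc compare-methods --manifest cohort/manifest.csv --out errors.csv
```

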