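# Methods

## Quantitation

**ADC.** The two-point mono-exponential inversion
`ADC = ln(S0/Sb)/b` is exact for noiseless signals; with b = 800 s/mm²
and ADC reported in 10⁻³ mm²/s the implementation multiplies by 10³.
Voxels that cannot be inverted (`S0 ≤ 0`, `Sb ≤ 0`, or apparent signal
gain `Sb > S0`, which Rician noise produces at low SNR) are clamped to
ADC = 0 and counted in `meta['n_clamped']` — clamping rather than
masking keeps grids congruent; the count makes the degradation visible.

**SUV.** Body-weight SUV with the 1 g/mL tissue-density convention:
`SUV = C·W·1000 / (A·10⁶)` with C in Bq/mL, W in kg, and A the injected
activity decay-corrected to scan start, `A = A₀·2^(−Δt/T½)`,
T½ = 4057.7 s (Ga-68). The positron branching factor (0.89) is carried
as dose-record metadata only; it enters scanner-side reconstruction,
which this pipeline does not model. `suv_to_activity` is the exact
algebraic inverse, used by the phantom to render activity volumes.

## Mask thresholding

SUVmax is taken over the manual lesion ROI on the **reference** PET; the
mask at p% keeps ROI voxels with `SUV ≥ (p/100)·SUVmax`, inequality
inclusive, so the argmax voxel survives every threshold and no mask can
be empty for p ≤ 100. The same reference-derived mask is applied to
every PET method and to the ADC map, so cross-method feature differences
reflect voxel values, never segmentation differences. Masks thresholded
at increasing percentages are nested by construction and thresholding a
mask again at its own percentage is the identity (the SUVmax voxel is
inside every mask, so the cutoff is unchanged).

## Histogram features

Mean, max, min, median (midpoint convention for even n), skewness and
kurtosis on raw voxel values — no binning. Shape statistics use
population central moments with divisor n: `g1 = m₃/m₂^1.5` and excess
(Fisher) kurtosis `m₄/m₂² − 3`, so platykurtic regions are negative.
Regions below 4 voxels are rejected (fourth moments are meaningless),
as are constant regions (no histogram shape; this occurs only on
deliberately degenerate inputs such as a noise-free uniform field).

## Correlation and method comparison

**Spearman rho** is computed from average ranks (midranks for ties) and
the Pearson formula on ranks. Two-sided p-values: exhaustive permutation
of one rank vector for n < 8 (exact, ≤ 5040 permutations), the
t-approximation with n − 2 degrees of freedom otherwise. Constant
columns are rejected; in a correlation grid such cells are reported as
missing (NaN), never as zero. No multiple-testing correction is applied
across the 36 grid cells — the grid reports raw rho and p at nominal
alpha, which is the convention for exploratory feature heatmaps; callers
can correct downstream if they need decisions rather than description.

**avg.RAE.** The voxel-level form averages `|Pₓ − P_ref|/P_ref · 100`
over a region, excluding (and counting) voxels with reference ≤ 10⁻⁶.
For method comparison, the scalar N = 1 case is applied per subject to
each SUV feature and averaged over the cohort (mean ± sd per feature per
method), because one error per feature is the natural cohort summary.
Subjects whose reference feature is within 0.05 of zero are excluded
from that feature's cell with a logged count: excess kurtosis crosses
zero, where relative error is unbounded and meaningless. Methods are
compared per feature with a two-sided paired t-test on the per-subject
errors, with the Mann–Whitney–Wilcoxon test (exact for combined n ≤ 12
without ties, tie-corrected normal approximation otherwise) as the
nonparametric companion.

## The phantom

**Geometry.** Nested ellipsoids on a 64×64×32 grid at 2.604×2.604×3.12 mm
(a typical Dixon-resolution PET/MR grid): body (75, 75, 45) mm
semi-axes, prostate (24, 24, 18) mm, lesion ≈ (9, 9, 6.5) mm placed
posteriorly for peripheral-zone subjects and anterocentrally for
transitional-zone subjects (≈ 100 lesion voxels). Boundaries are sharp
(piecewise-constant truth): this keeps the programmed lesion means
exactly recoverable and leaves all within-ROI texture to noise and
smoothing.

**Tissue values.** Background ADC 1.4 ×10⁻³ mm²/s and SUV 2.0 (benign
prostate scale); lesion ADC drawn in [0.6, 1.1] ×10⁻³ mm²/s and lesion
SUV in [5, 17], spanning the clinically reported range for PSMA-avid
prostate cancer.

**Coupling.** Cohort lesion values come from a Gaussian copula with
latent correlation `r = 2·sin(π·ρ/6)`, which makes the population
Spearman correlation of the uniform marginals exactly the programmed
`coupling_rho` (default −0.5, matching the inverse ADC–SUV relationship
the analysis is designed to detect). At ρ = ±1 the pairs are exactly
co/antimonotone. The sample Spearman of 27 draws is slightly attenuated
(expectation ≈ −0.484 at ρ = −0.5), which is a property of the statistic,
not of the generator.

**DWI.** `S0 = 1000` inside the body, `S(b) = S0·exp(−b·ADC)`, then
Rician noise `sqrt((s+n₁)² + n₂²)` with σ = 0.02·S0 per channel — a
high-but-realistic SNR for averaged prostate DWI at b ≤ 800.

**PET.** The SUV truth is converted to activity through a per-subject
dose record (injected activity ~ N(174, 26²) MBq truncated to
[115, 250], body weight ~ N(80, 12²) kg truncated to [55, 110], fixed
1 h uptake delay), multiplied by the AC bias field, degraded with
additive Gaussian noise of σ = 0.05 SUV-equivalent, then smoothed with a
3 mm FWHM isotropic Gaussian and clipped at zero.

**AC bias emulator.** Each non-reference method multiplies the
reference activity by `1 + f`, where `f` is white noise smoothed at the
stated correlation length and standardized per realization to zero mean
and sd = amplitude. Since `f` is Gaussian, the expected voxelwise
avg.RAE against the reference is `amplitude·sqrt(2/π)·100` percent, and
avg.RAE is exactly linear in amplitude for a fixed seed — hence monotone.
The defaults (MRI-like amplitude 0.055, DL-like 0.031, correlation
length 4 mm) were calibrated once so the cohort avg.RAE of SUV_mean sits
near 2.7% and 1.5% respectively with kurtosis errors an order of
magnitude larger — the error pattern reported for Dixon-based versus
deep-learning-based attenuation correction — and are fixed thereafter.
The spatial scale of real AC error inside the prostate is not an
observable this package can inherit, so the correlation length is a
phenomenological knob, not a physical estimate.

**Seeds.** Every generator is a pure function of (spec, seed). Child
seeds derive from the master via `numpy.random.SeedSequence([seed, key])`
with fixed keys (dose 0, DWI noise 1–2, bias fields (10, offset), PET
noise (20, offset), cohort marginals 99, subject i 100+i), so any
subject regenerates individually and bit-identically.

## Problem sizes

The default phantom runs a 27-subject cohort in ≈ 2 s (three PET
methods). Replicate (Monte-Carlo) studies — type-I error and coupling
recovery, 200 cohorts each — use `PhantomSpec.compact()`: the same
prostate/lesion geometry on a 48×48×24 grid with a trimmed body
ellipsoid, roughly halving per-subject cost without touching any
quantity those studies measure (all features live inside the lesion).

## What the phantom does and does not show

Passing tests demonstrate that the pipeline recovers programmed
couplings, respects mask algebra, and reproduces the calibrated AC error
ordering. The phantom deliberately omits: intra-lesion texture (truth is
homogeneous, so percentage thresholds up to 60% usually retain the whole
ROI and correlation grids vary little across threshold levels — on
clinical data, lesion heterogeneity makes the threshold series
informative); anatomically realistic organ shapes; MR k-space physics
and distortions; PET sinogram/list-mode effects and true attenuation
physics (the bias emulator is phenomenological); registration error
(all grids are congruent by construction, and the pipeline refuses
incongruent inputs rather than resampling). Conclusions about real
PET/MR data therefore rest on the correctness of the computations, not
on the phantom's realism.

## Numerical and degenerate-input choices

- Congruence tolerance for loaded volumes: spacings within 10⁻³ mm.
- avg.RAE reference floor ε = 10⁻⁶ (voxel level); feature-level
  reference floor 0.05 (kurtosis near zero).
- Noiseless recovery is exact to float precision; with 3 mm smoothing,
  the ROI SUV_mean of a homogeneous lesion is pulled toward background
  by edge voxels — up to ≈ 12% for a high-contrast lesion on this grid
  (documented tolerance in tests).
- Median of an even-length list is the midpoint of the central order
  statistics; ranks use midranks for ties.
- SUV/activity round trips are exact inverse pairs to ≤ 10⁻¹² relative.
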