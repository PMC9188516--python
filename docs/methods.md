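# Methods

## Signal models

**Inversion-recovery spin echo (T1).** The voxel signal is modelled as
S(TI) = M₀ · exp(−TE/T2) · (1 − p·exp(−TI/T1) + exp(−TR/T1)). The
exp(−TR/T1) term accounts for incomplete longitudinal recovery at finite
TR; the dimensionless factor p ∈ (0, 2] absorbs B1 errors from imperfect
180° inversion pulses (p = 2 corresponds to perfect inversion, p = 0
removes the inversion term entirely). T2 is not a free parameter of this
fit: it is fixed per voxel from the preceding spin-echo fit, so the IR fit
estimates (M₀, p, T1) only.

**Multi-echo decay (T2, T2*).** S(TE) = S₀·exp(−TE/T2); the same
implementation serves T2 (12 spin echoes, 9.8–117.6 ms) and T2* (12
gradient echoes, 5.79–50.94 ms) — the sequences differ only in echo list
and TR, not algorithmically. The spin-echo list is an arithmetic
progression with step 9.8 ms; its third element is taken as 29.4 ms.

**Diffusion.** S(g) = S₀·exp(−b·gᵀDg) with a symmetric 3×3 tensor D in
mm²/s, b = 2000 s/mm², 64 unit directions (spherical Fibonacci lattice;
any set with ≥ 6 non-collinear directions determines D) and 3 b=0 volumes.
MD = tr(D)/3; FA = √(3/2)·‖λ − MD‖₂/‖λ‖₂ on the eigenvalues.

**Noise.** Magnitude MRI noise is Rician: |S + n₁ + i·n₂| with iid
zero-mean Gaussians of SD σ. σ is specified in signal units; the phantom's
M₀ is 700–1000 a.u., so σ = 5 corresponds to roughly 0.5–0.7% of the
unattenuated signal.

## Fitting

All relaxometry fits use trust-region-reflective least squares
(`scipy.optimize.least_squares`, analytic Jacobians, relative tolerances
1e-10, 500-evaluation cap, parameters scaled by their initial values).
The mono-exponential fit is initialized from the log-linear regression of
log S on TE; voxels with non-decaying or all-zero signals are flagged
invalid (NaN) rather than raising, and invalid voxels are excluded from
all downstream statistics. The IR fit is initialized with p = 2, T1 from
the zero-crossing TI (T1 ≈ TI_null/ln 2) and M₀ from the longest-TI
sample.

Magnitude IR data lose the sign of the recovery curve. Polarity is
restored by exhaustive prefix search: for every k = 0…n, the first k
inversion times are negated, the model fitted (cheap screening pass,
tolerance 1e-6), and the lowest-residual candidate re-fitted at full
tolerance. How the original study handled magnitude IR data is not stated;
this restoration scheme is this package's choice and reproduces the signed
fit exactly on noiseless data.

The tensor fit is unweighted OLS on log-signals against the design
[1, −b·gₓ², −b·g_y², −b·g_z², −2b·gₓg_y, −2b·gₓg_z, −2b·g_yg_z]; b=0
volumes are averaged into one sample first. Weighted or nonlinear variants
are out of scope. Non-positive DW signals are clamped to 1e-6·S₀ and
flagged; negative eigenvalues are clamped to zero for MD/FA and flagged
per voxel.

## Region aggregation

Voxels with tissue partial-volume fraction below 1 are excluded outright.
Remaining contamination on each parameter map is removed per region by
Otsu's method: the histogram threshold (256 bins) maximizing between-class
variance σ_b²(k) = w₁w₂(μ₁ − μ₂)². Between well-separated modes the
objective is exactly flat across empty bins; ties are broken at the
midpoint of the maximal plateau, placing the threshold mid-gap. Which side
of the threshold survives is set by `keep_rule` (default: majority class).
Two guards protect unimodal maps, where Otsu has nothing to separate: the
refined mask is rejected (full mask kept, with a warning) if more than 50%
of the region would be discarded or if the between-class variance explains
less than 70% of the total variance. The region mean is the arithmetic
mean over retained voxels; deep gray matter is aggregated as the union of
its four segmented nuclei.

## Temperature models and statistics

Each region × parameter is modelled as y = a + b·T (T in °C, one data
point per subject — subject-level means, never voxel pooling across
subjects), fitted by OLS twice: with and without the in vivo subjects.
CIs are t-based on n−2 degrees of freedom; adjusted
R² = 1 − (1−R²)(n−1)/(n−2); the p value is the two-sided slope t test,
equivalent to the Pearson correlation test. p values are reported
unadjusted across the 35 region × parameter combinations (a deliberate
mirror of the source analysis; multiple-testing correction would be needed
for confirmatory use). Whether the original CIs were t-based is not
stated; t-based OLS CIs are this package's documented choice.

Δ\* = 100·(ŷ_wo(36.5) − ȳ_invivo)/ȳ_invivo compares the
post-mortem-only extrapolation at 36.5 °C with the measured in vivo mean;
large values indicate non-temperature physiological effects.
Δ\*\* = 100·(ŷ_wo(4) − ŷ_wo(36.5))/ŷ_wo(36.5) is the pure temperature
contribution over the attainable post mortem range (4 °C cooling chamber
to 36.5 °C body temperature); it is invariant to rescaling the parameter's
units.

Temperature correction transports a value along the fitted line:
v_corr = v + b·(T_ref − T_meas). It is exactly invertible and composes
additively in temperature. The default slope is the without-in-vivo
variant: the Δ\* analysis shows the with-in-vivo line is contaminated by
non-temperature effects (especially MD and FA), so it would over-correct
post mortem data.

## Packaged coefficients

`data/temperature_models.csv` holds the published linear-model
coefficients for 7 regions × 5 parameters × 2 variants: a, b, 95% CI
half-widths, adjusted R², p (values printed as "< 0.001" are stored as
0.001 with an upper-bound flag), Δ\* on with-in-vivo rows and Δ\*\* on
without-in-vivo rows. Recomputing Δ\*\* from the printed (a, b) pairs
reproduces the printed statistic within 0.5 percentage points for 26 of 35
rows; the other nine carry slopes printed at 1–2 significant figures, and
`validate_against_paper` flags them as rounding-limited.

## Synthetic data

**Phantom.** Nested geometric compartments in a cubic grid (normalized
radius: cortex shell 0.70–0.95, white matter interior, four deep-gray
nuclei of radius 0.22, central CSF sphere of radius 0.15) — deliberately
non-anatomical; anatomy, B0 inhomogeneity, k-space effects and motion are
out of scope. Every labeled voxel takes its region's model value
a + b·T at the subject's brain temperature, perturbed by multiplicative
Gaussian within-region variation (default CV 3%; the source data report
region SDs only graphically, so the magnitude is configurable, not
asserted). Tensors are prolate and axisymmetric with the region's MD and
FA (white matter coherently oriented). Compartment-boundary voxels get
partial-volume fraction 0.6; interior voxels 1.0. CSF values are fixed
plausible constants (T1 4000 ms, T2 1800 ms, MD 2.0e-3 mm²/s) — CSF exists
to supply partial-volume contamination, not for analysis. The inversion
factor is p = 2 everywhere by default; fits expose p as a free parameter
and recover perturbed values when configured.

**Cohort.** 16 post mortem subjects with brain temperatures drawn from a
normal(12.7, 5.7 °C) truncated to [5.6, 28.1] (matching the study
population; note the truncated distribution's population mean is ≈13.8 °C)
plus 4 in vivo subjects at exactly 36.5 °C. Region means are the model
value plus Gaussian residual. Default residual SDs are backed out from the
published slope-CI half-widths (s = ci_b·√Sxx / t₀.₉₇₅,ₙ₋₂), anchoring the
synthetic noise to printed uncertainty since no residual SDs are printed.
`invivo_scale` multiplies the in vivo generating values per parameter to
emulate physiological post mortem offsets (e.g. scale 2.0 on MD emulates
the ~50% perfusion-driven MD drop and yields Δ\* ≈ −50%). Subjects draw
from per-index child seed streams, so cohorts are bit-reproducible and a
subject's data are invariant to cohort ordering or size.

**What passing tests do not show.** The generator produces data that obey
the linear model exactly (plus Gaussian noise); real brains add autolysis,
age effects, iron/myelin variation, segmentation error and registration
error. Recovery and coverage results on synthetic cohorts therefore
validate the estimation machinery, not the biological model.

## Problem sizes and defaults

Voxel-level demonstrations use 16³–20³ phantoms (≈1.5–3k labeled voxels),
chosen as the smallest grids in which every compartment retains
partial-volume-free interior voxels; the acceptance run fits one 16³
phantom plus 500 cohort-level replicates. Cohort-level analyses always use
the study-sized 16 + 4 cohort. All randomness flows from a single seed via
`numpy.random.SeedSequence` spawning.

## Known limitations

- The linear temperature model is a small-range approximation of the
  underlying exchange-model exponential; extrapolation far outside
  4–36.5 °C is unsupported (the correction warns outside 0–40 °C).
- Deep-gray nuclei are small in coarse phantoms, so their region means
  rest on few voxels and are correspondingly noisy.
- The Otsu guard thresholds (50% discard, 0.7 separability) are heuristics
  for unimodal maps; heavily contaminated regions (> 50% partial volume)
  would be left uncorrected by design.
- Rician bias is not corrected in the fits; at the default noise levels
  (≲1%) it is negligible relative to the reported error bands.
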