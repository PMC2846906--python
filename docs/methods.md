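# Methods

## Problem setting and model

The package targets two-class discrimination of mass-spectrometry
profiling matrices in the "wide" regime: each sample is a vector of
intensities over tens of thousands of m/z points, and the cohort holds at
most a few hundred samples. The pipeline composes three
classifier-independent preprocessing stages with a kernel classifier.

**Refining.** All spectra are aligned on the sorted union of their
observed m/z values; two observations share a row only when their m/z
values are *exactly* equal (no tolerance window — tolerance merging
would silently change the feature space, and the union-of-values
convention keeps alignment a pure set operation). Rows with any missing
cell are then removed, leaving a complete matrix. This is deliberately
conservative: at n samples and per-sample dropout rate q, a fraction
(1−q)^n of rows survives, so completeness is expensive at large n —
which mirrors how real high-resolution profiling matrices shrink by an
order of magnitude at this step.

**t-filtering.** Each row is tested for a class difference with a
two-sided two-sample t-test at significance level α (default 0.01). The
pooled-variance (Student) test is the default, Welch is available via
`equal_var=False`; the choice is exposed because neither is canonical
for this filter. No multiple-testing correction is applied — the filter
is a variable-selection heuristic retaining every row with nominal
p < α, not an inference procedure; an FDR-style correction would retain
far fewer rows and changes the method. A row with zero variance in both
classes and equal means carries no class signal and is assigned p = 1
(dropped); zero variance with different means is perfect separation and
is assigned p = 0 (kept). This avoids 0/0 without discarding genuinely
separating rows.

**Moment transform.** The surviving rows, in order, are partitioned
into consecutive windows of `width` points; the final partial window is
retained, so `m` rows give `⌈m/width⌉` windows. Window width counts
**points**, not Daltons: the dimension arithmetic (39,905 rows at width
40 → 998 windows → 3,992 four-moment features; 24,545 at width 50 → 491
→ 1,964) only works under the point reading, and it keeps the transform
well-defined after t-filtering, where the surviving rows are no longer
equally spaced in Daltons. Per window and sample the package computes
up to four moments with pinned conventions:

* mean `ΣY/N`; variance `Σ(Y−Ȳ)²/N` (population, N denominator);
* skewness `Σ(Y−Ȳ)³/(N·S³)` and kurtosis `Σ(Y−Ȳ)⁴/(N·S⁴)` with
  `S = √variance`, i.e. biased moment estimators and **raw** (non-excess)
  kurtosis — a normal window has kurtosis ≈ 3, not 0.

Zero-variance windows get skewness = kurtosis = 0 so constant segments
produce finite features. Feature rows are ordered window-major,
moment-minor. Mean and variance features are affine-equivariant
(y → a·y+b maps mean → a·mean+b, variance → a²·variance); skewness and
kurtosis are invariant for a > 0 — property-tested invariants that
document what intensity rescaling can and cannot change downstream.

**Kernel PLS.** Features are classified by partial least squares in dual
form. The polynomial kernel κ(x, z) = (⟨x, z⟩ + r)^p with p = 3, r = 1
by default builds the Gram matrix K; feature-space mean-centring is the
double-sided projection (I − 11ᵀ/n) K (I − 11ᵀ/n) for the training
block and its one-sided analogue (Kt − 1·1ᵀK/n)(I − 11ᵀ/n) for test
blocks. Latent scores come from the kernel-NIPALS recursion; for a
single ±1 response the inner loop closes in one step per component
(t ∝ K_deflated · y_deflated, normalised), after which K and y are
deflated by the extracted score direction. Prediction uses the standard
dual regression solution α = U(TᵀK_cU)⁻¹Tᵀy₀ built from the
*undeflated* centred kernel, with the response mean restored and the
label taken as the sign of the score (a score of exactly 0 maps to +1;
a measure-zero tie-break that keeps prediction deterministic). The
correctness anchor is the equivalence theorem: with a linear kernel
(p = 1, r = 0) the dual predictions coincide with classical primal
linear PLS regression; the test suite enforces agreement with an
independent implementation (scikit-learn's `PLSRegression`,
`scale=False`) to 1e−6 on random small instances, and with ordinary
least squares in the full-rank limit. Score vectors are kept
orthonormal (TᵀT = I to 1e−8, asserted). If deflation exhausts the
kernel's rank before the requested component count, the count is
reduced with a warning rather than producing degenerate directions.

The number of latent components has no canonical value; the default is
inner stratified 5-fold selection over 1..10 (ties toward the smaller
count, seeded and deterministic), with a fixed integer settable for
reproducibility. Features enter the kernel on their natural scales —
no standardisation — because the moment features carry meaningful
relative magnitudes and the transform's scale behaviour is documented
above.

## Validation

Accuracy, sensitivity and specificity are the usual confusion-matrix
ratios with cancer (+1) positive; CC is the Matthews correlation, defined
0 when a marginal factor vanishes. Sn/Sp are errors (not 0) when a class
is absent from the evaluation set, since every scheme here constructs
folds containing both classes. Three schemes are provided: stratified
five-fold cross-validation repeated R times (default 100), per-class
80/20 proportional hold-out repeated R times, and leave-one-out. Each
repeat pools its held-out predictions into one confusion matrix (one
MetricSet per repeat); means and SDs (N−1 denominator) aggregate over
repeats. Stratification avoids empty-class folds at the unbalanced class
sizes typical of case-control profiling.

**Leakage contract.** By default every fold refits the *entire*
pipeline — t-filter, width selection, component selection, KPLS — on the
training samples only. Filtering once on all data before cross-validation
(as some historical analyses did) leaks test information through the
filter; that protocol remains available behind an explicit
`global_preprocess=True` / `--paper-mode` switch so the two can be
compared, but it is never the default.

## Synthetic data generator

`momentpls.synth` generates cohorts with the structure the pipeline
assumes: a shared linear m/z grid (default 4,000 points over
700–12,000 Da); a baseline decaying as exp(−(mz−mz_min)/3000 Da) with
amplitude 20; 40 Gaussian peaks (width 20 Da ≈ 4σ) at locations shared
across samples, per-sample amplitudes N(30, 3²); 10 informative peaks
whose mean amplitude in the cancer class is shifted by
`effect_size × 3` (5 SDs by default); additive N(0, 0.5²) noise;
truncation at 0; and independent 2% per-point dropout. Defaults are
sized so that refinement at n = 60 keeps roughly 30% of the grid —
qualitatively the same completeness attrition seen in real
high-resolution matrices, at desk scale. Class signal is carried by peak
*amplitudes* at shared locations, not by peak-position shifts, because
amplitude differences are exactly what the t-filter and the moment
means/variances are built to detect; the generator stays analysable and
the null (effect_size = 0) is exactly exchangeable between classes.

What the generator does **not** emulate: isotope envelopes, chemical/
electronic noise structure, mass-calibration drift, intensity
heteroscedasticity across the m/z range, or batch effects. Passing
tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under the stated model, not clinical
performance on real serum profiles.

## Numerical and design choices

* Missing values are NaN internally; the on-disk token is configurable
  (default "NA", empty fields count as missing).
* Matrix round-trips are exact: files carry shortest round-trip float
  representations and are parsed with round-trip precision.
* Kernel centring checks symmetry to 1e−8 relative tolerance; centred
  row/column sums are validated in tests at 1e−10·n·max|K|.
* All randomness (fold draws, inner selection, generation) flows from
  explicit integer seeds through `numpy` generators; repeated runs with
  one seed are bitwise-identical, which the suite asserts.
* Validation harness sizes used in tests: cohorts of 20–60 samples,
  grids of 600–4,000 points, 2–10 repeats — chosen so the full suite
  completes in seconds while every statistical assertion retains a
  comfortable margin (e.g. the t-filter's type-I check uses 1,000 null
  rows against the 99% binomial band around α).

## Known limitations

* Exact-match union alignment assumes all spectra share one acquisition
  grid; instrument-specific m/z jitter would need upstream binning or
  calibration, which this package deliberately does not perform (no
  baseline subtraction, peak detection or normalisation either).
* The refine step's completeness requirement scales badly with cohort
  size at fixed dropout; at high n consider imputation upstream (out of
  scope here).
* Raw (non-excess) kurtosis is a pinned convention; an excess-kurtosis
  variant would shift features by a constant 3, which the polynomial
  kernel does not absorb, so conventions must not be mixed across train
  and test data.
* Only the polynomial kernel is tested; other kernels can be added via
  `KernelParams`-style extension but carry no guarantees from this
  suite.
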