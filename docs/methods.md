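# Methods

This note documents the models, estimators and numerical choices behind
voxelhub, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Data model and conventions

All images of a run share one grid; array indices are 0-based and the
NIfTI affine maps them to world millimetres.  Cluster tables report peak
coordinates in world mm.  TR precedence is config override > NIfTI
header, because headers are unreliable in practice.  Motion files carry
three translations (mm) and three rotations (degrees); the 2.0° exclusion
rule therefore applies to the native units, and rotations are converted
only where geometry needs radians.  One directory per pipeline stage,
per-subject NIfTI maps, TSV for every table; a `run_log.json` records the
seed, parameters and package version, and an `INCOMPLETE` marker flags
aborted runs.

## Preprocessing

The chain is fixed and logged: discard → motion QC → nuisance regression
→ band-pass → smoothing.

* **Volume discarding** removes the first 10 frames (signal
  equilibration): 240 acquired → 230 analysed.
* **Motion QC.**  Frame-wise displacement is the translation-only
  variant: the Euclidean norm of frame-to-frame translation differences,
  FD₀ = 0.  Rotations are screened separately by the 2.0° limit, so the
  two rules are not redundant.  The FD exclusion statistic is the
  subject's mean FD against the cohort mean + 2.5 SD of mean FDs; the QC
  report states the rule that fired.  (The base of the "2.5 SD" rule is
  ambiguous in the methodological literature; subject-mean-vs-cohort is
  the choice here and is flagged in the report.)
* **Nuisance regression** removes the Friston-24 expansion ([p, p²,
  p₋₁, p₋₁²] per rigid-body parameter, lags zero-filled at t = 0), the
  WM and CSF mean signals, an intercept and a linear trend, by voxel-wise
  OLS.  The linear trend is always included — resting-state drift removal
  and filter stability.  No global-signal regression.  Rank deficiency is
  an error naming the first collinear column.  Residualization is
  idempotent to 1e−8.
* **Band-pass** is a zero-phase frequency-domain mask (linear detrend,
  FFT, zero all bins outside 0.01–0.08 Hz including DC, inverse FFT) —
  the "ideal filter" of the REST/DPARSF family, which realizes the stated
  band exactly.  Measured on 230-frame sinusoids at TR = 2 s the 0.05 Hz
  gain is 0.999 and the 0.20 Hz gain 0.001.
* **Smoothing** is a separable Gaussian with σ = FWHM/(2√(2 ln 2)) per
  axis in voxel units (0.8493 voxels for 6 mm on 3 mm voxels), reflecting
  boundaries; the kernel is mass-preserving to 1e−6.  Smoothing position
  is configurable: `before_dc` smooths the 4-D data (the literal listed
  order of the emulated protocol), `after_dc` (default) computes
  correlations on unsmoothed data and smooths the DC z-map — smoothing
  before voxel-wise correlation inflates local DC, and the DC methodology
  this package follows smooths derivative maps.

## Degree centrality

Weighted DC sums the Pearson correlations strictly above r₀ (ties
excluded, negatives never contribute; binarized DC counts them).  The
implementation standardizes each in-mask series to zero mean and unit
norm, so correlation blocks are matrix products; blocks of rows are
correlated against all voxels, the diagonal is excluded by setting the
self-entry to −∞, and all five thresholds are accumulated in one pass.
This is bit-equivalent (≤1e−10, measured ~1e−14) to the naive all-pairs
double loop while keeping memory O(block × N).  Zero-variance voxels are
dropped from the mask with a logged warning.  z-scoring uses the sample
SD (ddof = 1); a constant DC map (degenerate inputs) yields a zero z-map
with a warning rather than an error.

## Seed-based functional connectivity

ROI mean series over ROI ∩ mask (explicit cluster masks or spheres by
center and radius, default 6 mm); Pearson correlation map; Fisher
z = atanh(r) with r clipped to 1 − 1e−7 so voxels identical to the seed
stay finite.  Zero-variance voxels get r = 0 with a log note.  No frame
scrubbing is applied anywhere (none is part of the emulated protocol).

## Group inference

The two-sample design codes group as patient = 1 / control = 0 with
mean-centered covariates (sex as a 0/1 indicator), so the contrast t is
the adjusted patient-minus-control difference and deficits are negative.
With no covariates the contrast t equals the pooled two-sample t to
machine precision (a test asserts 1e−8).  Standardized residuals
(voxel-wise e/√RSS) feed the smoothness estimator.

**Smoothness.**  For each axis, the variance v of first differences of
the standardized residual field over in-mask neighbor pairs estimates
2(1 − ρ(1)).  Rather than the small-lag limit FWHM = √(4 ln 2 / v), the
exact Gaussian-autocorrelation relation is inverted:
ρ(1) = 1 − v/2, FWHM = √(2 ln 2 / (−ln ρ(1))) — identical as v → 0 but
unbiased at the ~2-voxel FWHM this pipeline operates at (the small-lag
form overestimates by ~10% there, which materially shifts cluster
p-values).  The estimate is floored at 1 voxel; resels = mask voxels /
∏FWHM.  Simulation recovers a known 6 mm field within 2%.

**GRF cluster inference.**  The t map is Gaussianized by probability
matching (z = Φ⁻¹(F_t(t)), computed tail-wise to avoid underflow);
the two-tailed voxel p fixes u = Φ⁻¹(1 − p/2); each sign's excursion set
is labeled separately (26-connectivity default, configurable to 6/18).
Cluster-level p uses the stationary-field theory:
E[m] = R·(4 ln 2)^{3/2}(2π)⁻²(u² − 1)e^{−u²/2} (the 3-D Euler
characteristic density only — boundary terms are small for compact
masks), E[n] = R·Φ(−u)/E[m], P(N ≥ s) = exp(−β s^{2/3}) with
β = (Γ(5/2)/E[n])^{2/3}, and cluster p = 1 − exp(−E[m]·P(N ≥ s)).
Because the exact excursion behavior of a lattice field at 2-voxel FWHM
is not captured by any closed form, the procedure is validated by
Monte-Carlo calibration rather than value matching: on 200 null cohorts
of 6-mm-smoothed Gaussian maps (39 subjects, covariate-adjusted GLM) the
family-wise cluster false-positive rate measured 0.02 at nominal 0.05
two-tailed — inside the accepted [0.01, 0.10] band, on the conservative
side, which is the documented behavior of this inference family at low
smoothness-to-voxel ratios.

**Demographics.**  Continuous variables are tested per group for
normality with a one-sample Kolmogorov–Smirnov test against a normal
with the sample moments (no Lilliefors correction — only the branch
choice depends on it): both-normal → pooled-variance t-test, otherwise
Mann–Whitney U.  Sex uses the χ² contingency test (with continuity
correction); a 14M/5F vs 15M/5F split is correctly non-significant.

## Clinical screen

Cluster-mean DC z per subject; partial correlation of cluster means with
each clinical variable controlling age, sex (0/1) and education,
restricted to the patient group.  r is the Pearson correlation of the
OLS residuals of both variables on [1, covariates]; df = n − k − 2; the
two-tailed p comes from t = r√(df/(1 − r²)), which is exact under joint
normality (the null p-value distribution is uniform; a K-S test asserts
it).  Covariates constant within the group (e.g. a single-sex patient
sample in a small replicate) are dropped as uninformative.  Because no
specific multiplicity procedure is canonical here, the screen reports
raw p and Benjamini–Hochberg q across all screened cells and flags both.
Constant variables yield r = NA, never a flag.

A power note: with n = 19 patients and three covariates (df = 14), a
two-sided test at α = 0.05 of a true partial correlation of 0.6 has
power ≈ 0.73 even when the cluster mean is read out without noise
(Fisher-z argument: SE = 1/√13, critical r ≈ 0.497).  Screens at this
sample size should be treated as exploratory; the package reports the
measured detection rate rather than assuming a higher one.

## The synthetic cohort generator

Emulates a two-group study — 19 patients vs 20 controls, 240 frames at
TR = 2 s on a 3 mm isotropic 30×36×30 grid — with everything needed for
ground-truth verification and nothing hidden:

* **Anatomy phantom.**  Nested ellipsoids: a gray-matter shell
  (~7300 voxels), white-matter interior, CSF core — enough structure for
  tissue-signal extraction and mask logic, with no claim to realistic
  anatomy.
* **Signal model.**  y_v(t) = baseline + Σ_h λ_{v,h}·s_h(t) +
  λ_net·s_{p(v)}(t) + drift + AR(1) noise.  Hub latents s_h are
  band-limited (0.01–0.08 Hz, unit variance, exact by frequency-domain
  construction); λ_{v,h} is the subject's hub loading tapered by
  exp(−d²/2r²) inside the hub sphere and 0 outside.  Patients receive
  loading 0.4 vs 0.8 in controls at the default deficit hub (radius
  12 mm): the group effect is implanted in *correlation structure*, not
  amplitude, because DC measures connectivity.  AR(1) noise has
  innovation SD 0.5 and φ = 0.3 (stationary variance σ²/(1 − φ²),
  verified to 5%); drift is a linear plus ~0.004 Hz component below the
  passband.
* **Background networks.**  Gray matter is partitioned into 40 fixed
  Voronoi parcels (seeded deterministically; identical for all subjects
  — they play the role of anatomy), each with its own band-limited
  latent at loading 0.35 for every subject; hub spheres are carved out.
  Rationale: with a pure-noise background, band-pass filtering leaves
  ~64 effective temporal degrees of freedom, so voxel-wise DC is
  dominated by chance threshold crossings whose subject-level
  fluctuations are not shared by hub voxels (their noise-correlation
  share is attenuated by the hub variance); the within-mask z-scoring
  then injects that fluctuation straight into the hub readout.  Real
  gray matter is network-organized and real DC fields are dominated by
  genuine connectivity; the parcels reproduce that regime, and with them
  the implanted deficit expresses as a stable cohort effect (peak
  |t| ≈ 4–11 across seeds, matching the magnitudes such studies report)
  instead of a seed-lottery.
* **Between-subject variance** comes from per-subject hub-loading jitter
  (SD 0.1) — also the handle the covariate model couples to.
* **Covariates** are drawn from the demographic and clinical moments of
  the emulated cohort (age ≈ 62.7 ± 5.9 vs 60.8 ± 6.3, education
  5.5 ± 3.2 vs 6.3 ± 2.7, 14/19 vs 15/20 male, FEV1 46.1 ± 20.6 vs
  97.1 ± 16.9 %predicted, etc.).  A chosen target variable (default
  FEV1) is built as μ + σ(ρ·z + √(1 − ρ²)ε) from the standardized
  within-group loading jitter z, so its population partial correlation
  with the jitter given age/sex/education is exactly ρ_target.  The
  manifest records both the absolute loading and the jitter; correlation
  checks use the jitter because the absolute loading is confounded with
  the group effect by construction.
* **Motion** traces are generated, not estimated (realignment is out of
  scope): heavily smoothed noise scaled to ~0.2 mm/0.2°, far inside the
  exclusion limits, with an optional `excludable` subject that violates
  the 2.0 mm rule for QC testing.
* **Determinism.**  One spec seed; per-subject seeds are spawned from it;
  two runs produce bit-identical directory trees.  The JSON manifest
  (spec, per-subject seeds and loadings, ρ_target) suffices to regenerate
  every injected effect.

What the generator does **not** emulate: physiological (cardiac or
respiratory) noise, susceptibility artifacts, spatial nonstationarity of
smoothness, realistic anatomy or registration error.  Tests passing on
this generator therefore demonstrate the *statistical machinery* —
exactness of the estimators, calibration of the inference, recovery of
effects of known size — not robustness to those acquisition artifacts.

## Problem sizes used in verification

The end-to-end recovery check runs the full default cohort (39 subjects
× 230 frames × ~7300 mask voxels, all five thresholds from a single
correlation pass, ~2–3 minutes single-threaded).  GRF calibration uses
200 null cohorts of smoothed Gaussian z-maps — the inference stage's
actual input — because full BOLD synthesis for 200 cohorts would add
hours without exercising any additional code path.  Oracle-equivalence
checks use 200–500 voxel instances where the all-pairs reference is
computable in seconds.  The clinical power replicate uses the covariate
model with a noise-free cluster-mean readout, an upper bound on the
power of the full chain.

## Known limitations

* GRF cluster p-values at 2-voxel FWHM are conservative (measured FWER
  0.02 at nominal 0.05); at higher smoothness-to-voxel ratios the
  calibration tightens.  Permutation inference is out of scope.
* The ideal band-pass assumes on-grid behavior; off-grid sinusoids leak
  slightly (passband gain bounded within [0.9, 1.1]).
* The pipeline holds preprocessed 4-D data in memory (float32) between
  the DC and FC stages; at full MNI grids with large cohorts, enable
  `preprocess.save_bold` and stream from disk instead.
* Peak-level GRF p-values, eigenvector centrality and anatomical
  labeling of clusters are not implemented.
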