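# Methods

## Scope and model

`urinemet` implements a two-class urine ¹H-NMR screening analysis: binned
spectral features, a single-response OPLS-DA classifier validated on a
stratified hold-out set, S-TOCSY-based marker annotation, and standard
diagnostic statistics. The synthetic-data module generates the cohorts the
rest of the package is tested on; it is a first-class, tested component,
not a fixture.

## Synthetic cohort generator

**What it emulates.** 1D CPMG-style urine spectra on an ascending 14-ppm
window ([−0.5, 13.5] ppm, 32768 points by default) at a 500.13-MHz proton
frequency. Each spectrum is a sum of Lorentzian multiplets (default FWHM
0.0015 ppm) for a template library comprising:

- nine marker metabolites at their literature shifts and multiplicities
  (alanine 1.49 d; citrate 2.54 d, 2.68 d; creatine 3.04 s; creatinine
  3.05 s, 4.07 s; glycerol 3.57/3.66/3.78 m; hippurate 3.98 d, 7.55 t,
  7.64 t, 7.83 m; phenylalanine 7.32/7.38/7.42 m; taurine 3.27 t, 3.43 t;
  3-hydroxybutyrate 1.21 d), with cancer-vs-control directions
  up/up/up/down/down/up/up/up/down respectively;
- a TSP reference singlet at 0.00 ppm with fixed amplitude;
- a marker-free background matrix (urea, acetate, succinate,
  dimethylglycine, histidine, trigonelline, formate) whose peaks keep
  > 0.02 ppm clearance from every marker peak centre;
- a broad Gaussian residual-water band (FWHM 0.2 ppm) centred at 4.88 ppm,
  large enough to be the global maximum of the raw spectrum so the
  exclusion logic is exercised non-trivially;
- additive Gaussian baseline noise with standard deviation expressed as a
  fraction of the TSP peak height (default 0.002).

J-couplings are not observable after 0.0073-ppm binning, so typical
literature values are used (alanine 7.2 Hz, 3-hydroxybutyrate 6.3 Hz,
taurine 6.6 Hz, citrate AB 15.1 Hz, hippurate/phenylalanine ≈7.5–7.8 Hz).
The generic "multiplet" is rendered as four equal Lorentzians spanning
2 J — a symmetric stand-in for unresolved higher-order patterns; only peak
positions matter downstream.

**Concentration model.** Per subject, each metabolite concentration is
drawn lognormally with coefficient of variation `subject_cv` (default 0.3)
around its group mean; cancer means are the control means times
2^(±effect_log2fc) with sign from the marker's direction. Creatine and
creatinine share a latent subject factor with opposite signs (default
strength 0.6), reproducing their observed inverse within-subject
relationship. The cancer group carries TNM stage labels in the proportion
56 IA : 13 IB : 10 II : 15 III : 9 IV per 103 cases, so stage-subgroup
analyses have realistic strata.

**Calibrated effect size.** The source study reports only directions of
change, not magnitudes, so the default per-marker effect had to be chosen
once such that the full pipeline operates in the ≥ 90%
sensitivity/specificity regime at ~100 subjects per group. With this
generator (background matrix included) that calibration gives
`effect_log2fc = 0.8` (a 1.74-fold mean shift per marker). It was fixed
once and is configurable.

**Background matrix scale.** Baseline concentrations put the nine markers
at roughly 15% of the retained spectral area, dominated by urea — the
realistic regime for urine. This matters because total-area normalization
induces closure: if markers carried a large share of the total area, their
group shift would leak an artifactual anticorrelation into every other
bin. At the chosen composition, background bins stay below the S-TOCSY
reporting threshold in almost all seeds, which is also what the source
analysis implicitly assumes when it reports only nine metabolites.

**What it does not emulate.** Time-domain FID physics (relaxation, CPMG
echo modulation), pH-dependent chemical-shift drift, baseline distortion
and phasing errors, peak-position jitter between subjects, and urine
dilution variation (which total-area normalization would remove exactly
and would therefore test nothing). Passing tests demonstrate the
chemometrics recovers planted structure under realistic variability; they
do not certify performance on real spectra, where shift drift and baseline
artifacts add failure modes this generator omits.

## Preprocessing

Fixed order: **reference → exclude → bin → normalize**.

- TSP referencing shifts the axis so the tallest point in [−0.2, 0.2] ppm
  sits at exactly 0; a flat window is an error.
- Exclusion removes the water region 4.62–5.15 ppm (closed interval) and,
  by default, the TSP region ±0.05 ppm — the reference compound is not
  biological signal and must not enter the total-area denominator. Both
  happen before normalization so the dominant water signal cannot swamp
  the total area. Both regions are configurable.
- Binning tiles [origin, axis max) with half-open [left, left + width)
  buckets of width 0.0073 ppm, anchored at the retained axis minimum
  (configurable `bin_origin`; nothing anchors the grid canonically, so a
  deterministic choice was made). A bin's value is the sum of intensities
  at the grid points inside it times the median grid spacing — an area —
  and bins containing no grid points (inside exclusions) are dropped. All
  spectra of a cohort are binned on one shared edge layout; a mismatch is
  a hard error.
- Total-area normalization divides each row by its own sum; negative noise
  intensities pass through binning untouched and only a nonpositive row
  total is an error.

## OPLS-DA

Single-y NIPALS: for each of `n_ortho` rounds, compute the PLS weight
w ∝ Xᵀy (unit norm), scores t = Xw, loadings p = Xᵀt/(tᵀt), take the
component of p orthogonal to w as the orthogonal weight w_o, deflate
X ← X − t_o p_oᵀ with t_o = X w_o; finally fit the predictive component on
the deflated matrix. Predictions for new samples apply the training
centring (mean-centring by default; unit-variance and Pareto scaling
available), strip the orthogonal components sequentially, and project on
w. Mean-centring is the default because unit-variance scaling inflates
pure-noise bins at 0.0073-ppm resolution.

Numerical choices: NIPALS tolerance 1e−10 on the weight change, max 500
iterations, failure raises; n_ortho ≥ rank of centred X is rejected; an
orthogonal round that finds no class-orthogonal variation left (‖w_o‖ <
1e−12) stops early rather than fabricating a component. Class coding is
fixed at control = 0 / cancer = 1 with decision cutoff 0.5; a prediction
exactly at the cutoff is called cancer.

Q² uses stratified 7-fold cross-validation (scikit-learn fold assignment,
seeded): Q² = 1 − PRESS/TSS with PRESS accumulated over held-out
predictions. The hold-out validation split and the k-fold Q² are separate
mechanisms: the first measures diagnostic performance, the second model
stability on the training set.

## S-TOCSY and annotation

P(corr)p is the Pearson correlation and Pp the (n−1)-normalized covariance
of each bin with the driver. The default driver is the OPLS predictive
score, sign-oriented so cancer scores higher, making covariance signs read
directly as up/down in cancer; a bin index can be used instead for classic
STOCSY. Constant bins report correlation 0, not NaN.

Annotation: a template peak matches when a bin intersecting ±0.02 ppm of
its centre carries |P(corr)p| ≥ 0.3 (threshold chosen well below the
"rather small, ≤ 0.7" correlations typical of multi-contributor urine
signatures; configurable). The direction call comes from the passing bin
**nearest the peak centre**, not the strongest bin in the window: with
near-degenerate resonances (creatine 3.04 vs creatinine 3.05) the
strongest bin in a ±0.02-ppm window can belong to the neighbouring
metabolite and would invert the call. The reported `max_abs_corr` is still
the strongest passing bin in the window.

## Diagnostics

- Split: per stratum, round(n/3) samples (half-up) go to validation,
  seeded and disjoint; 103/100 gives 34/33.
- Sensitivity/specificity are percentages rounded half-up to one decimal
  (clinical-table convention); cancer is always the positive class.
  Note: published companion tables sometimes transpose the two labels
  relative to the count-based text; this package follows the counts —
  sensitivity is the correctly-predicted fraction of cancers.
- ROC sweeps the unique scores (ties grouped into single steps); the
  trapezoidal AUC then equals the tie-corrected Mann–Whitney concordance.
  The Youden point maximizes sensitivity + specificity − 1; exact values
  are reported, not rounded to tens.
- The univariate panel uses two-sided Mann–Whitney tests (rank-based,
  robust to the lognormal concentration distributions; a t-test is
  available) with Benjamini–Hochberg adjustment.
- The volcano filter keeps fold change ≥ 1.5 or ≤ 1/1.5 and FDR ≤ 0.005,
  both boundaries inclusive.
- Stage-subgroup models are metadata filters (keep all controls, keep
  cases whose stage is in the filter) applied before the split — not
  separate code paths.

## Pipeline and reproducibility

One master seed is forked via `numpy.random.SeedSequence.spawn` into
independent per-stage seeds (simulation, split, cross-validation), so any
stage is replayable in isolation. Reports are canonical JSON — sorted
keys, floats rounded to 12 significant digits — making determinism
testable by byte comparison. Wall-clock timestamps go to a separate
`run.log`, never into the report, so identical config + seed produces
byte-identical reports. Errors abort with the failing stage's name.

The per-metabolite AUC table scores each marker by the normalized
intensity of the bin nearest its first template peak; for markers whose
direction is "down" the score is negated before the ROC so AUC > 0.5
always reads as discriminative, the convention of single-feature ROC
panels.

## Problem sizes

The test suite runs reduced cohorts (20–30 subjects per group, 8192-point
grids) for unit-level checks and the full default cohort (103 cancer /
100 control, 32768 points) for the end-to-end plant-and-recover run; the
full pipeline completes in a few seconds. Null calibrations use 20
replicates (Q² on 40 × 200 noise matrices) and 10 replicates (AUC on 2000
uninformative scores).

## Known limitations

- R²Y/Q² values on synthetic cohorts characterize the generator, not any
  real patient population; the published 86.5%/72.8% depend on undeposited
  spectra and are not reproducible targets.
- No peak alignment: the generator has no shift jitter, so none is
  needed; real data would require it before binning at 0.0073 ppm.
- Q² can be optimistic when classes are heavily unbalanced within small
  folds; the stratified folds mitigate but do not eliminate this.
- The OPLS implementation is single-response (two-class) only.
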