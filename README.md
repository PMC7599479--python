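# urinemet

A Python toolkit for two-class urine ¹H-NMR metabolomics screening studies,
built around the workflow used to discriminate early gastric cancer patients
from healthy controls by urine NMR profiling: spectral preprocessing,
OPLS-DA classification with a held-out validation set, S-TOCSY marker
identification, and ROC/confusion diagnostics. Because no patient spectra
from such studies are publicly deposited, the package ships a first-class
synthetic cohort simulator that generates seeded urine-like CPMG spectra
with known ground truth, so every stage of the pipeline is testable end to
end.

It is aimed at metabolomics researchers and methods developers who want a
reproducible, scriptable version of the classic SIMCA-style binned-NMR
discriminant workflow.

## The analysis

1. **Preprocessing.** Each 1D spectrum is referenced so the TSP singlet
   sits at 0 ppm, the water region (4.62–5.15 ppm) and the TSP region
   (±0.05 ppm) are excluded, the spectrum is bucketed into 0.0073-ppm bins
   (bin value = integrated area), and each sample's bin vector is divided
   by its own total area (total-area normalization), giving the feature
   matrix **X** (samples × bins, rows summing to 1).

2. **OPLS-DA.** With class codes *y* ∈ {0 = control, 1 = cancer}, the
   single-response orthogonal projections to latent structures model
   removes `n_ortho` components of X-variation orthogonal to *y* (default
   2), then fits one predictive PLS component on the deflated matrix:
   *ŷ = t·c + ȳ* with *t = X_filtered·w*. Fit quality is reported as
   R²Y = 1 − RSS/TSS on training data and Q², its cross-validated analogue
   from stratified 7-fold held-out predictions.

3. **Validation.** A stratified one-third hold-out split (e.g. 34 of 103
   cancers and 33 of 100 controls) is set aside before model fitting;
   validation samples are classified by thresholding *ŷ* at the a priori
   cutoff 0.5, yielding sensitivity = TP/(TP+FN) and
   specificity = TN/(TN+FP).

4. **S-TOCSY.** Every bin is correlated against a driver signal — by
   default the OPLS predictive score oriented so cancer scores higher —
   giving the correlation P(corr)p and covariance Pp profiles; bins with
   |P(corr)p| ≥ 0.3 near a template peak annotate that metabolite, and the
   covariance sign calls its direction of change in cancer.

5. **Diagnostics.** Per-metabolite ROC curves (tie-aware AUC = concordance
   probability, Youden operating point), Mann–Whitney tests with
   Benjamini–Hochberg FDR, pooled serum-tumor-marker arithmetic and a
   fold-change/FDR volcano filter round out the reporting.

## Worked example

```python
from urinemet.pipeline import RunConfig, run

report = run(RunConfig(seed=1))          # default: synthetic 103/100 cohort
v = report["validation"]
print(report["training"]["r2y"], report["training"]["q2"])
print(v["sensitivity_pct"], v["specificity_pct"])
print([h["metabolite"] for h in report["stocsy_hits"]])
```

prints (seed 1):

```
0.7517461133373652 0.7152247158233428
100.0 100.0
['creatinine', 'creatine', 'glycerol', 'taurine', 'hippurate', 'citrate',
 'alanine', '3-hydroxybutyrate', 'phenylalanine']
```

That is: the OPLS-DA model explains 75% of the class variance on training
data with a cross-validated Q² of 0.72; all 67 held-out samples are
classified correctly at the 0.5 cutoff; and S-TOCSY annotation recovers
exactly the nine planted marker metabolites (and no background
metabolite), each with the planted direction of change.

The same run is available from the shell:

```sh
urinemet run --seed 1 --out results/run1
urinemet simulate --out cohort/ --seed 7       # stage-wise use
urinemet preprocess --in cohort/spectra.csv --out matrix.csv
```

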