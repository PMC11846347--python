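# imfstat

Statistical analysis of **infrared molecular fingerprints** (IMFs) —
mid-infrared absorption spectra of blood serum — for studying disease
progression and patient survival, built around the lung-cancer
case-control + cohort study design: FTIR spectra of therapy-naive
patients, stage-stratified matched case-control classification, and
survival modelling over a ~4-year follow-up.

It is written for biostatisticians and spectroscopists who want the
full analysis chain as tested, reusable, seeded components rather than
a one-off script pile.

## What it computes

Given a spectral matrix (subjects × wavenumbers, cm⁻¹) and a cohort
table (demographics, TNM stage, follow-up):

1. **Preprocessing** — add back a scaled reference water spectrum
   (undoing instrument overcompensation), truncate to 1000–3000 cm⁻¹,
   remove the silent region (1850–2800 cm⁻¹, open interval), and
   L2-normalize each spectrum. The default 950–3050 cm⁻¹ grid at
   4 cm⁻¹ retains exactly 263 channels.
2. **Matching** — per tumor stage, optimal 1:1 case-control pairing on
   (age, sex, BMI): minimum-total-Mahalanobis-distance assignment
   restricted to pairs within a propensity-score caliper
   (0.2 SD of the logit propensity).
3. **Differential fingerprints** — per-wavenumber mean difference
   (cases − controls) with the control SD, per-wavenumber Cohen's *d*,
   and the scalar mean effect size (mean |d| across wavenumbers).
4. **Classification** — L2-logistic regression in stratified 10-fold
   CV with an inner penalty grid search; mean ROC by vertical
   averaging; AUC mean ± SD. Learning curves (5 repeats per subset
   size) extrapolated with the inverse power law AUC(n) = a − b·n⁻ᶜ.
5. **ROC-GLM** — the binormal model ROC(t) = Φ(α₀ + α₁Φ⁻¹(t)) extended
   with covariates, g(ROC_Z(t)) = h₀(t) + βZ (probit g and h₀), fitted
   semiparametrically through placement values of leave-one-out SVM
   scores; inference by case/control-stratified bootstrap with Wald
   statistics. This is the instrument for asking whether tumor stage
   shifts the diagnostic ROC curve *after* accounting for sample size.
6. **Survival** — Kaplan-Meier curves and log-rank tests by
   sex/operability/stage/histology; ridge-penalized Cox proportional
   hazards on the full spectral fingerprint, scored by Harrell's
   C-index in nested cross-validation (10 outer folds, penalty chosen
   by 3-fold inner CV); associations of the out-of-fold hazard score
   with stage (point-biserial) and with time to death (Pearson).

Because the original patient data are not public, the package ships a
first-class **synthetic cohort generator**: serum-like baseline bands,
a fixed disease signature whose amplitude grows with stage, structured
between-subject band variation, truncated-normal demographics per
stage, and Weibull proportional-hazards survival with administrative
censoring and dropout. Every analysis is exercised end-to-end on it,
reproducibly from one seed.

## Worked example

```python
import numpy as np
from imfstat import (SyntheticConfig, simulate_cohort, preprocess,
                     match, differential_fingerprint, fit_logistic_l2_cv,
                     nested_cv_cindex, survival_arm_config)
from imfstat.pipeline import default_preprocess_config

cfg = SyntheticConfig(seed=3)                 # 184 controls, 317 cases (stages I-IV)
matrix, cohort = simulate_cohort(cfg)
spectra = preprocess(matrix, default_preprocess_config(
    matrix.wavenumbers, cfg.water_overcompensation))
print(spectra.n_wavenumbers)                  # 263

controls = cohort[cohort.group == "control"]
stage4 = cohort[(cohort.group == "case") & (cohort.stage == 4)]
design = match(stage4, controls)
cases_m = spectra.select_subjects(design.pairs.case_id.tolist())
ctrls_m = spectra.select_subjects(design.pairs.control_id.tolist())
fp = differential_fingerprint(cases_m, ctrls_m)
X = np.vstack([cases_m.absorbance, ctrls_m.absorbance])
y = np.r_[np.ones(design.n_pairs, int), np.zeros(design.n_pairs, int)]
cv = fit_logistic_l2_cv(X, y, folds=10, seed=0)
print(f"stage IV: {design.n_pairs} pairs, AUC {cv.mean_auc:.3f} "
      f"+- {cv.sd_auc:.3f}, mean effect size {fp.mean_effect_size:.3f}")
# stage IV: 138 pairs, AUC 0.962 +- 0.031, mean effect size 0.544
```

The mean AUC is the average over the ten held-out folds: at stage IV
the fingerprint separates cases from matched controls almost
perfectly, and the mean effect size (average |Cohen's d| per
wavenumber) quantifies the same disease signal without reference to
any classifier. Earlier stages give smaller values of both — run the
same block with `stage == 1` to see the near-chance end.

The survival arm mirrors the 160-patient cohort design:

```python
cfg = survival_arm_config(seed=3)             # 160 patients, 95 with known stage
matrix, cohort = simulate_cohort(cfg)
spectra = preprocess(matrix, default_preprocess_config(
    matrix.wavenumbers, cfg.water_overcompensation))
cv = nested_cv_cindex(spectra.absorbance,
                      cohort.time_days.to_numpy(), cohort.event.to_numpy(), seed=0)
print(f"nested-CV C-index {cv.mean:.2f} +- {cv.sd:.2f}")
# nested-CV C-index 0.70 +- 0.07
```

A C-index of 0.5 would mean the fingerprint carries no ranking
information about who dies sooner; values near 0.68 say the spectrum
taken at diagnosis is genuinely prognostic under the generator's
default conditions.

There is also a thin CLI (`imfstat simulate|preprocess|match|classify|
roc-glm|learning-curve|survival|run-all`) that wraps the same
functions and writes JSON/CSV reports.

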