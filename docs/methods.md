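# Methods

This note documents the statistical machinery in `imfstat`, the
assumptions behind it, the choices made where the design was genuinely
open, and what the synthetic cohort does and does not emulate.

## Spectral preprocessing

Serum FTIR spectra arrive on a uniform wavenumber grid (default
950–3050 cm⁻¹ at 4 cm⁻¹ resolution, 526 channels). Four steps run in a
fixed order: (1) a scaled reference water spectrum is *added*, undoing
the instrument's tendency to overcompensate the water background of a
liquid sample; (2) spectra are truncated to the closed interval
[1000, 3000] cm⁻¹; (3) the biologically silent region is removed as the
*open* interval (1850, 2800) cm⁻¹ — grid points landing exactly on the
endpoints are retained; (4) each spectrum is scaled to unit Euclidean
norm. On the default grid this leaves exactly 263 channels. The order
is load-bearing (normalization does not commute with truncation) and is
guarded by a test.

The water-correction scale is a configuration constant, not estimated
from the data; estimating the instrument-specific overcompensation is
out of scope and documented as a limitation. The open/closed interval
conventions are fixed here for testability; either convention at the
silent-region endpoints would be defensible.

## Matched case-control designs

Per tumor stage, cases are paired 1:1 to healthy controls on age, sex
(0/1) and BMI. A logit propensity model on the three covariates
defines admissibility: a pair is admissible when its logit-propensity
difference is within 0.2 × SD of the pooled logit propensity (the
standard caliper convention; nothing in the study design pins a
width). Among admissible pairs the design minimizes the *total*
Mahalanobis distance (pooled covariance, ridge 1e-8 if singular) via
minimum-cost bipartite assignment — optimal matching, not greedy, and
tested against exhaustive permutation enumeration on small instances.
Cases without an admissible control are dropped with a logged warning.
If the propensity logit separates completely (common in tiny strata),
matching falls back to caliper-free optimal matching with a warning
rather than failing the design. One control pool may serve several
stage-specific designs; within one design each control is used at most
once.

## Differential fingerprints and effect sizes

The differential fingerprint is the per-wavenumber mean absorbance
difference (cases − controls), displayed against the control-group SD.
The standardized summary is per-wavenumber Cohen's *d* with pooled SD;
the scalar **mean effect size** is the mean of |d| across wavenumbers.
The absolute value matters: the disease pattern oscillates in sign
across the spectrum, so a signed average would cancel. How exactly the
effect-size average should be formed was an open choice; |d| averaging
reproduces the intended monotone growth of fingerprint magnitude with
stage. Note that mean |d| is upward-biased in small groups (the folded
sampling noise of d̂ contributes ≈ √(2/π)·SE(d̂) under the null), so
comparisons across groups of very different size must be made with
equal amplitudes in mind; the powered acceptance checks average over
replicate cohorts for this reason.

## Classification and learning curves

Case-vs-control classifiers are L2-penalized logistic regressions
evaluated in stratified 10-fold CV; the inverse-regularization constant
is chosen per outer fold by an inner 3-fold grid search over 7
log-spaced values (1e-3…1e3) with AUC as criterion. Mean ROC curves
are obtained by vertical averaging of fold ROCs at 101 evenly spaced
FPR points; AUC is summarized as mean ± SD over folds. Class imbalance
is handled by stratification only — matched designs are balanced by
construction.

Learning curves train on random class-balanced subsets of increasing
size (5 repeats per size, averaged) and are extrapolated with the
inverse power law AUC(n) = a − b·n⁻ᶜ fitted by bounded nonlinear least
squares (a ∈ (0.5, 1], b ≥ 0, c > 0, multiple c starts). A flat curve
degenerates gracefully to b → 0 with a at the constant level. Note the
asymptote can hit the a = 1 bound when the largest subsets already
classify nearly perfectly.

The continuous scores feeding the ROC-GLM come from a linear-kernel
SVM evaluated by leave-one-out CV (decision-function values, not
thresholded). The SVM cost constant is unspecified in the underlying
design; it defaults to C = 1 with an override. Leave-one-out scores
carry a small pessimistic bias under the null (the left-out subject's
class is underrepresented in training), which vanishes with cohort
size; this is a property of the protocol, not a defect.

## Binormal ROC model and ROC-GLM

The binormal model writes ROC(t) = Φ(α₀ + α₁Φ⁻¹(t)) with
AUC = Φ(α₀/√(1+α₁²)); when case and control scores are normal with
means μ₁, μ₀ and SDs σ₁, σ₀, α₀ = (μ₁−μ₀)/σ₁ and α₁ = σ₀/σ₁. The
covariate extension models g(ROC_Z(t)) = h₀(t) + βZ; both the link g
and the baseline h₀ are taken probit, so the baseline remains binormal.

Fitting is semiparametric via placement values: each case score s maps
to PV = 1 − F₀(s) with F₀ the empirical control ECDF; the indicators
U_it = 1{PV_i ≤ t} over the FPR grid t = 0.01…0.99 (99 points; Φ⁻¹
diverges at the endpoints) have mean ROC_Z(t), so a probit GLM of U on
{1, Φ⁻¹(t), Z, Z·Φ⁻¹(t)} estimates (α₀, α₁, β_intercept, β_slope). The
GLM is solved by a dedicated IRLS routine (cross-checked against a
general GLM implementation at 1e-6) because bootstrap inference and
size studies need tens of thousands of refits.

Point estimates deliberately ignore the within-case correlation of the
U_it; **all inference is bootstrap**: cases (with covariates) and
controls are resampled separately, each resample refitted, SE taken as
the SD of coefficient draws (default 1000 draws), and two-sided p from
the Wald statistic against the standard normal. Failed refits are
skipped and counted, with >10% failures aborting. The covariate enters
as centered ordinal stage (1–4); indicator coding is available. The
Wald test's type-I error is verified at ≈5% by simulation. Coefficient
reports include β_intercept and β_slope separately; which single
hypothesis a given analysis should emphasize is application-dependent,
so all are reported.

## Survival analysis

Kaplan-Meier estimation and the k-sample log-rank test are delegated to
`lifelines`; pairwise log-rank p-values are reported raw *and*
Holm-adjusted because the adjustment convention in the motivating
design is unstated.

The prognostic model is Cox proportional hazards on all spectral
channels, ridge-penalized — with p ≈ 263 features against n ≈ 160
subjects only regularization makes the fit identified — maximizing
loglik(β) − penalty·‖β‖²/2 with Breslow tie handling via Newton
iterations (`scikit-survival` backend; non-convergence is flagged,
never silent). The hyperparameter grid is the ridge penalty over 7
log-spaced values (1e-2…1e4).

Scoring is honest nested CV: 10 outer folds stratified by the event
indicator; within each outer training fold a 3-fold inner CV picks the
penalty with the best mean held-out Harrell's C; the refitted model is
scored on the outer test fold. Harrell's C counts, over comparable
pairs (the shorter observed time ends in an event), the fraction where
the shorter-lived subject has the higher risk score, ties in the score
counting ½; the implementation is vectorized and tested for exact
agreement with an O(n²) pair-enumeration oracle under censoring.

Out-of-fold linear predictors are centered within each fold before
being pooled (fold models share no common origin); the "hazard rate"
used in association analyses is exp(linear predictor), i.e. the
relative risk. Associations reported: point-biserial correlation of
the hazard score with binarized stage (I/II vs III/IV) plus an ordinal
Pearson variant (the binarization convention is not pinned by the
design, so both are given), and the Pearson correlation of hazard with
observed time among deceased subjects. Under this sign convention
higher hazard pairs with *shorter* time, so the expected correlation is
negative; analyses that report a positive "hazard vs time" association
are using the magnitude or a reversed axis, and the package logs the
convention explicitly.

## Synthetic cohort generator

The generator produces the study conditions everything above is tested
under.

**Spectra.** A fixed serum-like baseline is a sum of 7 Gaussian bands:
five broad protein/carbohydrate humps spanning 1000–1700 cm⁻¹ (ending
in amide II ≈1560 and amide I ≈1660 cm⁻¹) and two lipid CH-stretch
bands near 2900 cm⁻¹. Between-subject biological variation multiplies
each band height by (1 + N(0, subject_sd)) independently
(subject_sd = 0.05), giving structured low-rank covariance that
survives L2 normalization — a pure global-scale subject effect would be
removed by the normalization and make classification unrealistically
easy against detector noise alone. White per-channel noise
(noise_sd = 0.003 a.u.) models the detector floor. The instrument
water overcompensation subtracts a fixed water reference (OH bending
≈1643, association band ≈2130, stretch and libration tails) scaled by
a config constant, so the preprocessing correction can be tested as an
exact inverse.

**Disease signature.** A fixed, unit-L2-norm, alternating-sign mixture
of the *same* five broad protein/carbohydrate components, added with a
stage-dependent amplitude (controls 0). Placing the signature inside
the span of the natural variation components is deliberate: a
classifier must then compete with biology rather than only with white
noise, which keeps per-stage AUCs in a realistic range while the
per-channel effect sizes remain substantial. Default amplitudes
(0.025, 0.085, 0.14, 0.22 for stages I–IV) are calibration knobs — the
underlying study reports no effect-size scale — chosen once, by a
pre-registered power analysis against the default variation scales, to
place stage AUCs at roughly 0.6/0.7/0.85/0.95 and to make the stage
trends in AUC and mean effect size resolvable at the study's uneven
per-stage sample sizes (39/33/94/151 cases vs 184 controls).

**Demographics.** Truncated normals (age 18–95, BMI 15–50) with
per-group parameters mirroring the study table (e.g. stage IV: n=151,
age 68±9, 52% female, BMI 25±5); sex as Bernoulli(%female). Histology
(AC/SCC/LCC/other ≈ 65/27.5/4.5/3%) and stage-dependent operability
are included so the survival arm's stratified analyses have material
to work on.

**Survival.** Event times follow a Weibull proportional-hazards model
(shape 1.2, baseline scale 26000 days) with linear predictor
0.35·stage + 16·amplitude by default; observed time is the minimum of
event time, independent exponential dropout (5e-5/day) and the
administrative horizon (1460 days ≈ 4 years), yielding ≈50% events —
the censoring structure of a 4-year oncology cohort. The survival-arm
helper reproduces the cohort layout: 160 patients, stage recorded for
95 (17/9/32/37), missing for 65; stage-unknown patients carry a latent
stage (uniform) that drives their biology, and are excluded from
stage-stratified analyses only. Synthetic clinical markers are the
true linear predictor plus N(0,1) noise.

**What the generator does not emulate** — and hence what green tests do
*not* establish about real serum data: instrument noise physics, batch
and drift effects, real biochemical band shapes and their covariance,
comorbidity structure, informative censoring, and any particular
numerical AUC/C-index of a real cohort. Passing tests establish that
the *statistical machinery* behaves correctly (oracle agreement,
calibration, power under known signal), not that a given clinical
performance level would be attained.

## Numerical conventions and degenerate inputs

- Empirical AUC uses the Mann-Whitney statistic with ties counted ½;
  the step ROC and rank AUC agree with trapezoidal integration.
- Zero pooled SD at a wavenumber sets d = 0 with a warning; all-zero
  SD errors. Zero spectra cannot be L2-normalized and error with the
  subject named.
- The probit IRLS clips the linear predictor to ±8 and probabilities
  away from 0/1 by 1e-10; convergence at max |Δβ| < 1e-10 or 50
  iterations.
- Cox fits converge at relative tolerance 1e-7 within 100 Newton
  iterations; non-convergence is carried as a flag on the model.
- Bootstrap refits that degenerate (e.g. constant resampled covariate)
  are skipped and counted; the run aborts beyond 10% failures.
- All seeds are explicit; identical seeds give bit-identical spectra,
  tables, fold assignments and bootstrap draws.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the case-control arm at the
full study layout (501 subjects) and the survival arm at n=160, with
bootstrap draws reduced to 120–300 and replicate counts of 3–20 for
the powered end-to-end properties; statistical calibration checks use
200 simulations. These sizes were chosen so the complete verification
runs comfortably on a single CPU while keeping every assertion's
Monte-Carlo error well inside its tolerance band.
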