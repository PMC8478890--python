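# Methods

## The model

A walking trip is observed as a 1 Hz heart-rate series, a 1-min PM2.5/PM10
series on the same clock, and a per-minute subjective safe/risk label.
Analysis proceeds on 60 s half-open windows [kΔ, (k+1)Δ). For volunteer v
with resting baseline t(v) (mean of a 10-min seated measurement in clean
air), window i carries the heart-rate change rate

    r_i = (t_i − t(v)) / t(v)

which is dimensionless, may be negative, and is comparable across
volunteers and days. Health-risk state is modelled in two stages.

**Stage 1 (personal threshold).** For each volunteer independently, r_i
is swept against the subjective labels over a threshold grid with spacing
0.005 spanning [min r − 0.005, max r + 0.005]. A window is *judged* risk
iff r_i ≥ θ; cross-tabulation against the labels gives (Z_TP, Z_FN, Z_FP,
Z_TN), sensitivity T = Z_TP/(Z_TP+Z_FN), false-positive rate
F = Z_FP/(Z_FP+Z_TN) and Youden index J = T − F. The cutpoint is the
J-maximising grid value, ties broken by smaller F then smaller θ (the
upper-left preference on the ROC). AUC is the trapezoid over the (F, T)
points with (0,0) and (1,1) anchors, and AUC > 0.9 flags the curve
reliable. Because the same HR% cutpoint is attained at several PM2.5
concentrations during a walk, the personal PM2.5 threshold is the mean of
`mean_pm25` over windows with |r_i − θ| ≤ tol, tol starting at half a grid
step and doubling (logged) until at least one window matches.

**Stage 2 (population risk model).** Windows are classified y = 1 iff
r_i ≥ θ(v) (the boundary counts as risk, matching the ROC judgment
direction) and pooled into the binary logit

    ln(p/(1−p)) = β₀ + β₁γ₁ + β₂γ₂ + β₃γ₃ + β₄γ₄ + β₅γ₅

with γ₁ = PM2.5 (μg/m³), γ₂ = 1 for male, γ₃ = 1 for youth, γ₄ = 1 for
BMI ∈ [18.5, 24] (both bounds inclusive), γ₅ = HR% in percentage points.
Reference levels are female, middle-aged, non-healthy BMI. HR% enters in
percentage points because the calibrated coefficient 0.108 "per unit of
HR%" is only sensible on that scale. Windows are treated as independent
observations; no per-volunteer random effect is modelled (a known
limitation, see below).

The MLE is Newton–Raphson / iteratively reweighted least squares,
implemented in full in `walkrisk.logit`: score X'(y − p), observed
information X'WX with W = diag(p(1−p)), step-halving whenever a full step
would lower the log-likelihood, convergence at |Δℓ| < 1e−8 or gradient
max-norm < 1e−6, cap 100 iterations. Standard errors are square roots of
the diagonal of the inverse observed information at the optimum. The Wald
statistic is reported in both conventions, z = β/SE and χ² = (β/SE)² with
1 df; the χ² column is primary and supplies the p-value. Published tables
of this model family print Wald values inconsistent with both conventions
given their own β and SE, so no attempt is made to reproduce any
particular printed Wald column. Odds ratios are Exp(β) per covariate
unit. Risk probability is always the logistic transform of the linear
predictor; `predict_risk` also carries an explicit odds-form evaluation
path, exp(η)/(1+exp(η)), kept as a separate branch for verification.

`CALIBRATED_COEFFICIENTS` = (−6.323, 0.056, −0.264, −0.393, −0.327,
0.108) is the published field calibration (368 volunteers, Xi'an arterial
road); it drives the preset risk curves. Risk curves are drawn per
(gender, age) group over a PM2.5 grid at fixed HR% and BMI flag — the HR%
value substituted is an explicit parameter (`hr_for_curves`, default 35
percentage points) because the curves are conditional on it and no
canonical value exists.

## The synthetic cohort generator

The generator (`walkrisk.cohort`) emulates the study design so the whole
pipeline is testable without field data. All randomness derives from one
root seed; each volunteer owns a substream keyed by a CRC32 of the
volunteer id, so outputs are independent of iteration order and
byte-reproducible.

**Cohort.** Default group sizes 112/97/85/74 (male-youth, female-youth,
male-middle-aged, female-middle-aged). Heights are gender-specific
normals (male 1.72 ± 0.07 m, female 1.60 ± 0.06 m, clipped), BMI ~
N(22.5, 3.5²) clipped to [16, 35] — ≈54% inside the healthy band — and
weight = BMI·H². Resting baselines ~ N(64, 5²) bpm clipped to [45, 110].

**Exposure trajectory.** PM2.5 is sampled every 60 s as a reflected
(triangle-fold) random walk on the configured range (default 0–300
μg/m³) with per-step noise SD 8 μg/m³ and a deterministic drift, of
random sign, whose total travel equals twice the range. The drift
guarantees every walk sweeps the full concentration band and therefore
crosses its volunteer's latent threshold — a pure driftless walk leaves a
non-trivial fraction of walks on one side of their threshold, which would
make the personal threshold undefined. The default walk lasts 3600 s
(60 windows), giving a mean per-window PM2.5 increment of ≈13 μg/m³.
PM10 = 20 + 1.5·PM2.5 + N(0, 10²), floored at PM2.5 (mass-fraction
consistency); the pooled PM2.5–PM10 correlation exceeds 0.99.

**Heart-rate response.** The 1-min PM2.5 series is expanded to 1 Hz by
zero-order hold (a per-minute detector reading held until the next
reading); heart rate is baseline + group response + N(0, hr_noise_sd²),
hr_noise_sd default 3 bpm. Young males respond linearly
(1.7 + 0.10·PM2.5 bpm); the other groups follow a monotone double-logistic
S-curve, offset + A·[σ((c−100)/25) + σ((c−180)/25)], with inflections
near 100 and 180 μg/m³. Offsets and amplitudes (female-youth 9.5/10.0,
male-middle 11.7/9.0, female-middle 15.2/8.5) were calibrated once so the
pooled walking heart rates per group approximate the published summary
statistics (means 80.69/84.14/85.29/88.25 bpm and their ordering
female-middle > male-middle > female-youth > male-youth). The zero-order
hold makes the window-mean heart rate at zero noise an exact monotone
function of that window's PM2.5 reading, which is what lets the ROC stage
recover latent thresholds exactly up to grid resolution.

**Latent thresholds and labels.** Each volunteer draws a latent PM2.5
risk threshold ~ N(group mean ± 12, 20²), where +12 applies to
healthy-BMI volunteers. The per-(gender, age) means 149.4/140.5/118.5/
109.5 μg/m³ are the additive-model solution whose cohort-weighted
marginals reproduce the published marginal means — males 136, females
127, youths 145, middle-aged 114 μg/m³ — to within 0.3 μg/m³ at the
default group sizes; the BMI shift reproduces the direction and rough
size of the published healthy/non-healthy split (132 vs 107) while moving
the gender/age marginals by under 1.1 μg/m³. A window is labelled risk
iff its PM2.5 reading exceeds the latent threshold; labels then flip
independently with probability `label_noise`, default 0.05, chosen once
so the default cohort's fraction of reliable volunteers (AUC > 0.9)
matches the published 337/368 ≈ 0.92 (the default cohort at seed 1 gives
334/368 = 0.908).

**What the generator does not emulate.** No spatial route, weather,
traffic or PM chemistry; no circadian or exertion-driven heart-rate
dynamics (heart rate responds to concentration only, with no lag or
recovery kinetics); label errors are independent flips rather than
systematically biased self-reports; latent thresholds are independent of
the heart-rate response parameters. Tests passing on this cohort
therefore validate the estimation machinery under the stated generative
assumptions, not the physiological claims themselves.

## Numerical choices and degenerate inputs

- Aggregation windows are half-open; a trailing partial window is kept
  iff it spans at least half a window. Windows with no PM sample are
  excluded with a warning; labels attach only when the aggregation grid
  coincides with the 60 s label grid, otherwise windows are unlabeled.
- The window-length diagnostic regresses pooled window-mean heart rate on
  window-mean PM2.5 for each candidate window (30–300 s) and reports the
  overall regression F and its p-value; constant-PM pools are omitted
  with a warning. No window is auto-selected; 60 s is the documented
  default.
- The correlation screen reports |r| (absolute Pearson), unit diagonal;
  zero-variance columns give NaN with a warning; verbal strength bands at
  0.2 steps.
- Single-class label sets yield a flagged ROC curve with NaN AUC and
  `reliable=False`; threshold selection on such a curve raises. Such
  volunteers are excluded from the cohort summary and listed.
- Logit: single-class outcomes and constant covariate columns raise
  immediately (not identifiable). A coefficient escaping
  `separation_bound` (default 50) while the likelihood still improves
  raises a separation error naming the covariate. The default bound is
  conservative: on sharply separated data the iteration typically
  converges numerically (|Δℓ| < 1e−8 once |β| ≈ 22) before reaching it,
  so the escape is a safety net rather than a routine detector.
- All output tables are UTF-8 CSV with header rows and units in column
  names; one root seed governs the whole pipeline and is echoed in the
  run report.

## Problem sizes

The test suite exercises small cohorts (13–50 volunteers, 20–60 windows
each) for speed, plus one full 368-volunteer default cohort for the
group-ordering and reliability checks; the resimulation studies use
n = 10 000 for point recovery and 200 replicates of n = 368 for Wald
coverage. `scripts/acceptance.py` uses the same sizes and completes in a
few seconds.

## Known limitations

- **Grid quantisation of recovered thresholds.** The HR% cutpoint is a
  grid value just above the largest safe-side HR%, and the tie-break
  (smallest threshold at maximal Youden) together with the matching
  tolerance maps it to the last safe-side window. The recovered PM2.5
  threshold is therefore biased low by up to the trajectory's PM2.5 jump
  at the crossing; with the default trajectory (≈13 μg/m³ mean increment,
  noisy steps) the median zero-noise recovery error is ≈3 μg/m³, but for
  roughly one volunteer in ten the crossing jump exceeds the walk-mean
  increment. Recovery is exact in the limit of dense temporal sampling.
- **Small dummy-coefficient recovery.** With 0/1 covariates the Fisher
  information per observation is at most 1/16, so at n = 10 000 the
  standard error of a dummy slope cannot fall below 0.04. Slopes of
  magnitude ≈0.3 (as in the calibrated model) therefore carry ≈15%
  relative sampling error at that size, and single-dataset point
  estimates should be read with their confidence intervals, which do
  attain nominal coverage (94–98% observed for 95% intervals).
- **Independence assumption.** Windows within a volunteer are treated as
  independent in the logit; no clustering correction or random effect is
  applied, so reported standard errors understate uncertainty when the
  within-volunteer correlation is material.
- The Wald column of the published calibration table cannot be
  reconstructed from its own β and SE under either convention; this
  package reports both conventions computed from its own fits and leaves
  the discrepancy documented rather than patched.
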