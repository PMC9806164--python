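# Methods

`metsprog` implements a longitudinal pediatric metabolic-syndrome (MetS)
analysis: classification of MetS at two developmental stages, quantification
of prepuberty-to-puberty tracking of its components, and prediction of
pubertal MetS from prepubertal markers with fast-and-frugal trees (FFTs).
Because no individual-level cohort is distributed with the package, a
synthetic paired-cohort generator provides data with the statistical
structure the analyses assume; everything below describes what that model
does and does not capture.

## MetS definition

A child is classified as having MetS when obese — BMI strictly above the
sex- and age-specific obesity cutoff — and at least two of four components
are altered:

* hypertension: SBP **or** DBP above the sex/age/height-specific 95th
  percentile (configurable to SBP-only; which pressure drives the published
  pediatric flag is ambiguous, so both rules are exposed);
* hyperglycemia: fasting glucose strictly above 100 mg/dL;
* hypertriglyceridemia: TAG above the sex/age 95th percentile;
* low HDL-c: HDL below the sex/age 5th percentile.

All percentile comparisons are strict inequalities; a value exactly at a
cutoff is not altered, and a BMI exactly at the obesity cutoff is overweight,
not obese. Insulin resistance (HOMA-IR = glucose·insulin/405, Matthews
formulation for mg/dL and µU/mL) is flagged with cutoffs 2.5 (prepubertal),
3.38 (pubertal boys) and 3.905 (pubertal girls) but does not enter the MetS
rule; it is tracked as an auxiliary risk marker.

Percentile charts are pluggable CSV tables keyed by sex and age band (plus
height band for blood pressure). The bundled defaults are **synthetic**
smooth parametric curves in the broad range of published pediatric
references; they make the pipeline self-contained but are not authoritative.
Analyses of real cohorts must load the original reference tables in the
documented schema. BMI z-scores can be computed from a user-supplied LMS
table; the synthetic generator emits its own z-score column (below).

## Exclusion filters

Two filters applied in order, per paired subject, over the analyzed
phenotype set (BMI, BMI-z, WC, WHR, sum of skinfolds, SBP, DBP, TC, LDL-c,
HDL-c, TAG, glucose, insulin, HOMA-IR):

1. **Outliers** — subjects in the prepubertal normal-weight group with any
   analysis variable strictly above the cohort's empirical 99th percentile.
   The quantile is the linear-interpolation estimate computed per variable
   within each stage on the full pre-exclusion cohort. The rule never removes
   overweight or obese subjects.
2. **Missingness** — subjects with any missing analysis variable at either
   stage. No imputation is performed.

Because the p99 thresholds are re-estimated from whatever cohort the filter
receives, re-applying the filter to its own output with fresh thresholds can
flag a few additional rows. `apply_exclusions` therefore returns the
thresholds it used and accepts them back; re-application with frozen
thresholds is exactly idempotent.

## Synthetic cohort generator

The generator is group-first: each subject draws a prepubertal group
(normal weight / overweight / obesity without MetS / obesity with MetS, with
default weights 43:31:56:13 over 143), and all variables are drawn from
group-conditional marginals — log-normal except age, glucose, BMI-z and WHR
(normal). Within-subject tracking is a Gaussian copula per variable: the
pubertal latent is ρ·z_pre + √(1−ρ²)·ε with per-variable default ρ between
0.3 (glucose) and 0.7 (adiposity). BMI is constructed from the category
cutoffs themselves (an offset below the overweight cutoff for NW, a Beta
position within the band for OW, an offset above the obesity cutoff for OB),
so generated categories always agree with the classifier. BMI-category
transitions follow a 3×3 matrix whose diagonal encodes per-category
persistence 90.7% / 61.3% / 72.5% (overall 75.5%).

MetS status is emergent yet exact in expectation: subjects in the obesity-
MetS group are redrawn (rejection sampling on the component latents) until at
least two components are altered under the bundled charts, and obese non-MetS
subjects until at most one is. Pubertal MetS is drawn only among pubertal-
obese subjects of the two prepubertal obesity groups with probabilities
chosen so the expected case count is 17/143 with 4 persisting from the 13
prepubertal cases (risk ratio ≈ 3.1 for MetS tracking). Consequently the
expected classifier-derived prevalences are exactly 13/143 = 9.1% and
17/143 = 11.9%.

Internal consistency constraints: HOMA-IR is derived from generated glucose
and insulin (never drawn independently), insulin and glucose share a latent
correlation of 0.3, total cholesterol is LDL + HDL + TAG/5 with an LDL–HDL
latent correlation of 0.15, weight is BMI·height², hip is waist/WHR, and the
four skinfolds split the generated sum via a Dirichlet. Heights come from a
smooth synthetic growth curve with a subject-level offset shared across
stages (so pubertal height always exceeds prepubertal). The elapsed time
between stages is uniform on 5–8 years (only the stage-specific mean ages are
published; a uniform gap with mean 6.5 y reproduces them). Pubertal Tanner
stages are categorical over 2–5 per sex; the boys' distribution was chosen to
match the cohort-level Tanner SD, because the published per-sex SDs are
jointly inconsistent with the published total.

**Calibration.** Group-conditional means/SDs are taken from the published
group tables and then adjusted analytically at parameter construction so the
four-group mixture mean and SD equal the published cohort totals exactly
(the printed group tables and totals disagree at the 0.5–2% level, plausibly
from rounding and complete-case differences). Three small residual
multipliers (TAG SDs ×0.93/0.96, pubertal insulin SD ×0.97, TAG means −0.7/
−1.5 mg/dL) compensate the dispersion added by the MetS rejection step; they
were measured once with a calibration run at n = 50,000 and are fixed
defaults. At n = 50,000 every variable's mean is within max(3 SE, printed
rounding, 2%) of its target and every SD within 5%.

**What the generator does not emulate:** measurement error and digit
preference, seasonal/centre effects, non-monotone growth, realistic
cross-variable correlation beyond the group structure and the three explicit
couplings, informative dropout, and real reference-chart geometry. Passing
tests on synthetic cohorts demonstrate that the pipeline's estimators are
correct and well-calibrated under the stated model — not that the published
cohort-specific coefficients, AUCs or out-of-sample accuracies would be
reproduced on the real data (those require the non-deposited records and are
explicitly out of scope).

**Artifact injection.** `inject_artifacts` plants exactly `n_outliers`
normal-weight >p99 outliers (one inflated variable each, spread across
variable/stage slots) and blanks one field for `n_missing` further subjects.
So that the outlier filter flags exactly the configured count, natural
normal-weight extremes are first pulled back to the variable's median;
blanking precedes this step because the filter's quantiles are NaN-aware.
With zero counts the cohort is returned unchanged.

## Statistical tests

Stage-change tests are paired two-sided t-tests on the transform scale, and
prepubertal between-group contrasts are Welch tests. The transform policy is
log for every analysis variable except age, Tanner stage, glucose — and
BMI-z, which can be negative and stays on the identity scale. With exactly
two timepoints and complete pairs the paired t-test targets the same
within-subject contrast as a random-intercept mixed model; REML mixed models
and Kenward–Roger degrees of freedom are deliberately out of scope, and the
substitution is recorded in output metadata (`scale` column of the change
tables). P-value families are adjusted with the Benjamini–Yekutieli step-up
procedure (valid under arbitrary dependence; adjusted
p = min over larger p of m·c(m)·p₍ⱼ₎/j with c(m) the harmonic number), via
`statsmodels.multipletests(method="fdr_by")` behind the package surface.

Tracking effects are reported as risk ratios ((a/(a+b))/(c/(c+d)),
log-normal Wald CI) and odds ratios (ad/bc, Woolf CI), with the
Haldane–Anscombe +0.5 correction applied to all cells iff any cell is zero
(the method tag records it). `persistence_logistic` fits the same 2×2 (plus
optional sex/Tanner covariates) by maximum likelihood; without covariates it
reproduces the closed-form odds ratio, and perfect separation is returned as
a flagged estimate with an infinite bound. Which CI procedure produced the
published tracking interval is not derivable from the printed margins, so
the package always labels its own method and does not attempt to match that
interval.

## Fast-and-frugal trees

An FFT is an ordered list of single-variable threshold rules; every
non-final level exits on one side only, the final level classifies both
ways. Trees are scored by weighted accuracy

    wacc = (w·sens + spec) / (w + 1),

the ratio-normalized convex combination (w = 1.5 and 1.2 are the default
sensitivity weights; w = 1 is balanced accuracy). Construction is the "fan"
procedure: per-cue optimal thresholds on the full training set (all data
midpoints, both directions), cues ranked by marginal wacc, all 2^(depth−1)
exit assignments enumerated for each depth up to `max_depth` (default 4),
best training wacc wins. Ties break deterministically: higher sensitivity,
then fewer levels, then cue name order; threshold ties prefer the higher
sensitivity, then the lower threshold. On small instances the builder is
exhaustive-search-equivalent (tested against brute force). Note that
increasing w is guaranteed to never lower the selected sensitivity only over
a fixed candidate set (e.g. one cue's threshold grid); because the builder
re-thresholds and re-ranks cues per w, tree-level monotonicity can fail and
is not asserted.

`FastFrugalTreeClassifier` wraps the builder as a scikit-learn estimator
(get_params/set_params/fit/predict/score) so it composes with sklearn model
selection; `build_fft` and `FFTree` (JSON-serializable, with a text
rendering) are the functional interface.

## Validation scheme

Out-of-sample performance is estimated by stratified k-fold cross-validation
(k = 4, 5 repeats → 20 held-out estimates) with within-fold bootstrap
oversampling of the training partition only, ×25 by default. True
leave-one-out cannot stratify singleton folds or yield 20 estimates at five
repeats, so the stratified-k-fold reading is implemented with k
configurable. Held-out partitions are never resampled; train/test index
disjointness is asserted inside the loop. Baselines: single-cue ROC AUC
(rank/Mann–Whitney with tie correction) and backward stepwise logistic
regression (largest Wald p above `alpha_remove` = 0.05 removed per step;
`alpha_remove` = 1 keeps the full model, 0 empties it; separation is flagged
with infinite CIs). Multicollinearity is summarized by the maximum VIF,
1/(1−R²) of each predictor on the others.

## Numerical choices and degenerate inputs

Quantiles use NumPy's default linear interpolation everywhere. Wald
intervals use z = 1.96. Zero-variance paired differences, single-class
outcomes, constant cues, empty exposure arms and chart misses raise typed
errors rather than returning NaN. The pipeline fans one master seed into
per-stage sub-seeds through a fixed-order `SeedSequence` spawn, so any stage
can be re-run in isolation; all reported randomness is reproducible from the
single seed.

## Problem sizes used by the test suite and acceptance script

Calibration checks use one generated cohort of n = 50,000; structure
recovery uses 100 planted-rule cohorts of n = 2,000; stepwise recovery uses
n = 5,000; oracle-equivalence suites use 1,000 random small instances
(n ≤ 20), all 2×2 tables with cells ≤ 5, and 1,000 random p-vectors. These
sizes give stable Monte-Carlo margins for the stated tolerances while the
whole suite stays fast.

## Known limitations

* The bundled charts are synthetic; absolute flag rates on real data depend
  on loading authoritative references.
* The generator's group-conditional independence (beyond the explicit
  couplings) understates real biomarker correlation; emergent component
  tracking ratios are plausible but not calibrated to the published ones.
* Only two stages are modelled; no growth curves, no repeated measures
  beyond the pair, no imputation.
* Single MetS definition; alternative consensus definitions are not
  implemented.
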