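# Methods

## The index

LBSI is the residual of the allometric log–log regression of waist
circumference on weight and height,

LBSI = ln WC − c − a·ln W − b·ln H,

with WC and H in metres, W in kilograms and natural logarithms throughout.
The unit convention matters: only metres + natural log reproduce the Korean
reference population mean of about −0.02 when the rounded reference
coefficients (c, a, b) = (−2.69, 0.73, −1.06) are applied to typical Korean
adult anthropometry (WC 0.825 m, 63 kg, 1.60 m gives −0.0287).  Inputs in
centimetres are converted on load.  LBSIZ = (LBSI − μ)/σ with reference
(μ, σ) = (−0.02, 0.06); both the coefficients and the standardization
constants can be re-estimated in-sample (`fit_allometric_exponents`,
`estimate_standardization`) but the packaged reference set is never
silently replaced.

Two ABSI conventions coexist in the literature, differing in the sign of
the height exponent.  `compute_absi` defaults to the standard
WC·H^(5/6)/W^(2/3) form ("krakauer") and also offers the
WC/(W^(2/3)·H^(5/6)) variant ("as_printed") with a warning, since the
latter appears in print but is almost certainly a typo for the former.
Because every analysis here is rank-based or uses LBSI directly, the choice
does not affect any downstream result.

## Synthetic cohort

The generator emulates a middle-aged Korean population cohort followed for
ten years.  Per sex, (ln H, ln W) are bivariate normal (men: H 1.67 m,
W 66.8 kg; women: 1.53 m, 57.2 kg; log-scale SDs 0.033/0.14–0.15,
correlation 0.45); ln WC follows the allometric law plus N(0, 0.06) noise.
The generator's true intercept is −2.71 rather than the rounded scoring
value −2.69, so that LBSI *scored with the published constants* is centred
at the published reference mean of −0.02 — mimicking the small mismatch
between rounded reference constants and any particular cohort.  With these
defaults the simulated cohort reproduces the published baseline marginals:
WC 82.5 ± ~9 cm, BMI ≈ 24.5 ± 3.1 kg/m², LBSI SD 0.06.

Risk factors are drawn with the published marginals (age 52.1 ± 8.8 y;
SBP 121 ± 18 mmHg; TC 190 ± 35, HDL 45 ± 10 mg/dL; triglycerides
log-normal with mean 161 and SD 105 mg/dL, redrawn above the 400 mg/dL
Friedewald validity limit; smoking never/ex/current = 0.58/0.16/0.26;
diabetes/hypertension/dyslipidaemia prevalence 0.12/0.32/0.48).  LDL-C is
always computed by the Friedewald equation, never drawn, so the consistency
invariant holds exactly.

Event times are Weibull proportional hazards (exponential by default) by
inverse transform: H(t) = (t/scale)^shape·e^η with
η = β₁·LBSIZ + β₂·z(BMI)², z(BMI) standardized by the published reference
moments (24.5, 3.1).  The quadratic is the simplest smooth device giving
the J-shaped BMI dose–response reported for such cohorts while LBSIZ stays
log-linear.  The baseline scale is solved by root-finding at generation
time so the expected event fraction over the 10-year window equals
`target_event_rate` (default 0.07); follow-up is administratively censored
at 10 years.  Defaults β₁ = 0.5 and β₂ = 0.1 were fixed from the Gaussian
approximation AUC ≈ Φ(β/√2) — β₁ = 0.5 puts the LBSIZ AUC near the
reported ≈ 0.635, and β₂ = 0.1 makes the BMI J-shape comfortably
detectable at ~600 events.  One root seed is split into three documented
streams (anthropometry → covariates → outcomes), so extending one stage
never perturbs the draws of another.

What the simulator does **not** emulate: the hazard ignores age, blood
pressure and lipids (so the Framingham score is uninformative on synthetic
data, unlike in real cohorts, and its AUC sits near 0.5); there is no loss
to follow-up or competing mortality; covariates are mutually independent
beyond the allometric relation; the five CVD sub-diagnoses are collapsed
into one composite indicator.  Passing tests therefore demonstrate
correctness of the estimators and the qualitative phenomena (AUC ordering,
J-shape vs linearity), not real-data effect sizes for FRS-adjusted
quantities.

## Framingham risk score

The comparator is the continuous (Cox-model) general-CVD formulation with
sex-specific coefficients on ln age, ln TC, ln HDL-C, ln SBP (treated and
untreated), current smoking and diabetes; 10-year risk is
1 − S₀^exp(lp − mean lp).  The general-CVD version was chosen because the
composite endpoint (MI, CHD, CHF, cerebrovascular, PAD) matches "general
CVD" better than the older hard-CHD score; alternative coefficient tables
with the same YAML schema can be loaded by path, and the version id is
recorded in report metadata.  The packaged table reproduces the published
worked examples (e.g. the 61-year-old smoking woman at 10.48%).  No
recalibration to Korean incidence is performed.

## Survival analysis

* **Follow-up**: years = days/365.25 from baseline to the event or the
  administrative end of follow-up (default 2012-12-31), whichever is first.
* **Kaplan–Meier** estimation is delegated to lifelines; confidence bands
  are plain Greenwood (S ± 1.96·SE).  The log-rank test (2+ groups) is
  lifelines' multivariate form.
* **Cox PH** is fitted here by damped Newton on the partial likelihood with
  the Efron tie correction (default; Breslow switchable).  Covariates are
  internally centred and scaled to unit variance for conditioning and the
  fit is transformed back.  Step halving enforces a monotone
  log-likelihood.  Convergence requires gradient max-norm < 1e−6, or a
  Newton step below 1e−10 — the latter matters only for large cohorts
  (n ≈ 8500, hundreds of events) where the gradient's floating-point floor
  sits near 1e−6 while the coefficients are converged to machine precision.
  The implementation is cross-checked in the tests against lifelines
  (coefficients, SEs and log-likelihood to ≤1e−5) and against brute-force
  partial-likelihood maximization on a toy.
* **Deciles**: boundaries at the sample 10th–90th percentiles (linear
  interpolation); a value tied with a boundary goes to the lower decile;
  degenerate (tied) boundaries are an error.  Decile hazard ratios come
  from one Cox fit with nine indicators (decile 1 = reference, HR ≡ 1)
  plus the adjusters: age, sex, smoking (ex/current indicators), SBP,
  hypertension, diabetes, LDL-C, lipid-lowering medication.
* **Restricted cubic splines**: Harrell's truncated-power basis, 4 knots at
  the 5/35/65/95th percentiles by default (the standard placement for four
  knots), cubic terms scaled by (t_k − t_1)² for numerical balance; the
  function is linear beyond the boundary knots by construction.  The
  dose–response curve is HR(x) = exp(f(x) − f(ref)) with the reference at
  the exposure median by default and delta-method Wald bands from the
  basis-contrast covariance.  Nonlinearity is the joint Wald test of the
  k−2 cubic coefficients.
* All CIs are Wald on the log-HR scale.

## Discrimination

AUC is the midrank Mann–Whitney statistic, identical to the trapezoidal
integral of the empirical ROC curve (asserted to 1e−12 in tests).
Variances and the paired comparison of correlated AUCs use DeLong's
structural components; the variance estimate is validated against a
delete-one jackknife on small samples and calibrated type-I error
(0.05 ± 0.015 over 2000 null replicates) in the acceptance suite.  The
outcome is the binary 10-year event indicator — censoring time is ignored,
which is appropriate under near-complete administrative follow-up and is
recorded in report metadata.  The "integrated AUC" combines the Framingham
linear predictor with one obesity parameter via in-sample
maximum-likelihood logistic regression and compares the combined score
against FRS alone with the DeLong paired test; in-sample nesting makes the
combined AUC never meaningfully worse.  P-values are two-sided normal with
no multiple-testing correction.

## Baseline statistics

Continuous variables: equal-variance two-sample t-test (Welch by flag);
categorical: Pearson chi-square without continuity correction.  Spearman
correlations use midranks, so they are identical for LBSI and LBSIZ (a
tested invariance).

## Numerical and edge-case choices

* Anthropometry must be strictly positive; values outside plausible adult
  ranges warn but do not fail.
* Friedewald LDL-C is refused (not clipped) at TG ≥ 400 mg/dL.
* `estimate_standardization` uses the n−1 SD and refuses zero-variance
  input; `fit_allometric_exponents` requires n ≥ 3 and raises a
  collinearity error on rank-deficient designs, as does the Cox fitter.
* Allometric-recovery validation uses anthropometry spanning the full
  plausible adult range (weight 30–150 kg, height 1.35–1.95 m): the
  intercept of a log–log model is an extrapolation to ln = 0, so under a
  narrow cohort-like design its Monte-Carlo error is dominated by exponent
  uncertainty and a ±0.02 recovery band is unattainable regardless of
  implementation; the wide design isolates estimator correctness.
* Problem sizes in the test and acceptance suites (e.g. 24 spline
  replicates at n = 8485, 200-replicate coverage runs at n = 2000, 2000
  DeLong null replicates at n = 500) were chosen so each Monte-Carlo check
  has clear binomial resolution at its stated tolerance.

## Known limitations

No time-dependent ROC or Harrell's C; no competing risks, frailty or
time-varying covariates; no proportional-hazards diagnostics; FRS is not
recalibrated.  The synthetic cohort matches published marginals, not the
true joint distribution of any real population.
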