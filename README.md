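# lbsiz

Tools for **LBSIZ** — the z-score of the log-transformed A Body Shape Index —
and for the cardiovascular-risk analyses it is typically used in: ROC/AUC
discrimination against BMI, waist circumference and the Framingham risk
score, Kaplan–Meier and Cox proportional-hazards modelling, decile hazard
ratios and restricted-cubic-spline dose–response curves.  A calibrated
synthetic-cohort generator reproduces the statistical structure of a
middle-aged Korean population cohort followed for ten years, so the entire
pipeline runs end-to-end without access to restricted cohort data.

## The index

A Body Shape Index normalizes waist circumference (WC) for overall body
size through allometric scaling.  With population-specific exponents
estimated by the log–log regression

ln WC = c + a·ln weight + b·ln height + ε,

the log-transformed index is the regression residual

LBSI = ln WC − c − a·ln weight − b·ln height,

computed here with the Korean reference coefficients
(c, a, b) = (−2.69, 0.73, −1.06), WC and height in metres, weight in kg,
natural logarithms.  The z-score

LBSIZ = (LBSI − μ) / σ,  (μ, σ) = (−0.02, 0.06),

standardizes LBSI against the reference population.  Because LBSI is the
part of abdominal girth *not* explained by weight and height, LBSIZ is
nearly uncorrelated with BMI while remaining strongly associated with
central adiposity — which is why it discriminates cardiovascular events
better than BMI and shows a linear (rather than J-shaped) dose–response.

## Worked example

```python
>>> import lbsiz
>>> a = lbsiz.Anthropometry(wc_m=0.825, weight_kg=63.0, height_m=1.60)
>>> round(lbsiz.compute_lbsi(a), 4)
-0.0287
>>> round(lbsiz.standardize_lbsi(-0.0287), 3)
-0.145
>>> round(lbsiz.friedewald_ldl(190.4, 44.7, 160.8), 1)
113.5
```

A typical Korean adult (WC 82.5 cm, 63 kg, 160 cm) has LBSI −0.0287 —
close to the population mean −0.02 — hence LBSIZ −0.145, i.e. slightly
below-average abdominal girth for their body size.  The third call
recomputes LDL cholesterol from total cholesterol, HDL-C and triglycerides
with the Friedewald equation.

Full pipeline from the shell:

```bash
lbsiz simulate --n 8485 --seed 1 --out cohort.csv
lbsiz analyze --cohort cohort.csv --out report/ --figures
lbsiz report report/
```

which prints (seed 1):

```
n=8485 events=625 (v0.1.0)
AUC bmi     0.493 (0.468-0.518)
AUC wc_cm   0.567 (0.543-0.592)
AUC lbsiz   0.638 (0.616-0.661)
AUC frs     0.488 (0.465-0.512)
log-rank bmi     chi2=0.2 p=0.698
log-rank wc_cm   chi2=28.0 p=1.24e-07
log-rank lbsiz   chi2=77.3 p=1.5e-18
```

In the simulated cohort the hazard is log-linear in LBSIZ with a mild
quadratic in standardized BMI, so LBSIZ discriminates best, WC (correlated
with LBSIZ) comes second, and BMI — independent of the allometric residual —
adds almost nothing; the Framingham score is uninformative here because the
simulated hazard does not depend on its inputs.

## Layout

- `lbsiz.anthro` — BMI, ABSI, LBSI/LBSIZ, allometric regression, Friedewald LDL-C
- `lbsiz.simulate` — synthetic-cohort generator (anthropometry → covariates → outcomes)
- `lbsiz.framingham` — Framingham general-CVD 10-year risk (continuous Cox form)
- `lbsiz.survival` — follow-up construction, KM, log-rank, Cox PH, deciles, splines
- `lbsiz.discrimination` — ROC, Mann–Whitney AUC, DeLong tests, integrated AUC
- `lbsiz.pipeline` / `lbsiz.cli` — cohort I/O, baseline tables, end-to-end analysis

See `docs/methods.md` for the statistical methods and design choices.
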