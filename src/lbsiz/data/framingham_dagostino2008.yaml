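# Framingham general cardiovascular disease risk score (D'Agostino et al.,
# Circulation 2008), continuous Cox formulation.
#
# Linear predictor = sum of coefficient * transformed covariate:
#   ln(age), ln(total cholesterol), ln(HDL-C), ln(SBP) (separate coefficients
#   for treated / untreated blood pressure), current smoking (0/1),
#   diabetes (0/1).
# 10-year risk = 1 - S0 ^ exp(lp - mean_lp).
version_id: dagostino_2008_general_cvd
male:
  ln_age: 3.06117
  ln_tc: 1.12370
  ln_hdl: -0.93263
  ln_sbp_untreated: 1.93303
  ln_sbp_treated: 1.99881
  smoker: 0.65451
  diabetes: 0.57367
  s0_10yr: 0.88936
  mean_lp: 23.9802
female:
  ln_age: 2.32888
  ln_tc: 1.20904
  ln_hdl: -0.70833
  ln_sbp_untreated: 2.76157
  ln_sbp_treated: 2.82263
  smoker: 0.52873
  diabetes: 0.69154
  s0_10yr: 0.95012
  mean_lp: 26.1931
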