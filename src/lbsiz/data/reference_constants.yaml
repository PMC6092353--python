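# Named allometric coefficient sets for LBSI / LBSIZ.
#
# ln(WC_m) = intercept_c + weight_exp_a * ln(weight_kg) + height_exp_b * ln(height_m)
# LBSIZ = (LBSI - mean_lbsi) / sd_lbsi
#
# korean_kns_2018: scaling exponents from a log-log regression of waist
# circumference on weight and height in Korean adults, with the reference
# mean and SD of LBSI used for standardization.
korean_kns_2018:
  intercept_c: -2.69
  weight_exp_a: 0.73
  height_exp_b: -1.06
  mean_lbsi: -0.02
  sd_lbsi: 0.06
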