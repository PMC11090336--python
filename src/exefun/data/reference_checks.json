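{
  "chi_square_sex_by_genotype": {"younger": 0.99, "older": 1.34},
  "chi_square_p": {"younger": 0.61, "older": 0.51},
  "eta_sq_from_t": [[6.2, 98, 0.28], [2.45, 98, 0.06], [2.0, 98, 0.04]],
  "f_from_eta": {"eta_sq": 0.08, "f": 0.30},
  "d_from_f": {"f": 0.30, "d": 0.60},
  "tolerances": {"t": 0.02, "chi2": 0.02, "chi2_p": 0.02, "eta_sq": 0.005, "f": 0.01, "d": 0.005}
}
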