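indicator: third_molar
sex: male
source_id: synthetic:third_molar:male
type: type4
cohorts:
- n: 600
  mean_ca: 13.934453450705556
  sd_ca: 4.032504675521249
  mean_sa: 2.1266666666666665
  sd_sa: 1.916614525917288
  r: 0.9147094192875349
label_grid:
  C: 0.0
  D: 1.0
  E: 2.0
  F: 3.0
  G: 4.0
  H: 5.0
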