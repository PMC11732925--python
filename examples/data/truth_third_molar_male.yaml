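indicator: third_molar
sex: male
n: 2000
seed: 7
spec:
  family: continuation_ratio
  link: logit
  slope: non_parallel
intercepts:
- 12.65
- 14.3
- 14.5
- 14.58
- 14.8
slopes:
- -1.1
- -1.1
- -1.0
- -0.9
- -0.8
age_distribution:
  lower: 7.0
  upper: 21.0
  kind: uniform
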