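indicator: third_molar
sex: male
source_id: synthetic:third_molar:male
type: type3a
stages:
  C:
    n: 204
    mean: 9.597369532433433
    sd: 1.6696038918655107
  D:
    n: 66
    mean: 12.255800123786063
    sd: 1.7738661166919254
  E:
    n: 70
    mean: 14.173932764627576
    sd: 1.5527704564967193
  F:
    n: 69
    mean: 15.806825880819707
    sd: 1.7040405388661104
  G:
    n: 92
    mean: 17.452295558154653
    sd: 1.6129877092885008
  H:
    n: 99
    mean: 19.247155626124396
    sd: 1.3071266011519571
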