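indicator: third_molar
sex: male
source_id: synthetic:third_molar:male
type: type2
cohorts:
  7:
    C: 39
  8:
    C: 46
  9:
    C: 42
    D: 6
  10:
    C: 38
    D: 10
    E: 3
  11:
    C: 21
    D: 18
    E: 1
  12:
    C: 12
    D: 14
    E: 12
    F: 3
    G: 1
  13:
    C: 2
    D: 7
    E: 16
    F: 8
    G: 2
  14:
    C: 3
    D: 5
    E: 19
    F: 13
    G: 3
    H: 1
  15:
    D: 3
    E: 13
    F: 19
    G: 7
    H: 2
  16:
    C: 1
    D: 2
    E: 3
    F: 9
    G: 25
    H: 5
  17:
    D: 1
    E: 2
    F: 8
    G: 20
    H: 8
  18:
    E: 1
    F: 5
    G: 18
    H: 18
  19:
    F: 4
    G: 11
    H: 33
  20:
    G: 5
    H: 32
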