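indicator: third_molar
sex: male
source_id: synthetic:third_molar:male
type: type3b
stages:
  C:
    n: 204
    min: 7.027377804780961
    q1: 8.223410889294184
    median: 9.507477727771459
    q3: 10.586234211047662
    max: 16.029427012027725
  D:
    n: 66
    min: 9.04405950759185
    q1: 11.032403742882897
    median: 11.931751410508395
    q3: 13.187153846642284
    max: 17.738054806434356
  E:
    n: 70
    min: 10.827873827238642
    q1: 13.120704304967235
    median: 14.152002509783873
    q3: 15.18297361238383
    max: 18.928484680472422
  F:
    n: 69
    min: 12.254813824386584
    q1: 14.63937340168239
    median: 15.688168190639718
    q3: 16.81898183856694
    max: 19.9753623620174
  G:
    n: 92
    min: 12.933399726285531
    q1: 16.457681358934593
    median: 17.492522263734852
    q3: 18.481431549302233
    max: 20.76594532322602
  H:
    n: 99
    min: 14.971435508572272
    q1: 18.664378764555345
    median: 19.526692472588667
    q3: 20.254209813598084
    max: 20.941229384116536
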