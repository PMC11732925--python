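subject_id,sex,indicator,stage,age
syn-000000,male,third_molar,G,16.461638731737946
syn-000001,male,third_molar,C,10.000524817335608
syn-000002,male,third_molar,D,11.332328432343683
syn-000003,male,third_molar,G,18.192525354847664
syn-000004,male,third_molar,H,20.941229384116536
syn-000005,male,third_molar,C,8.991245413920725
syn-000006,male,third_molar,C,8.102157472667987
syn-000007,male,third_molar,C,9.531533391755964
syn-000008,male,third_molar,E,12.035056483650912
syn-000009,male,third_molar,C,9.374669495898676
syn-000010,male,third_molar,G,15.242630417556223
syn-000011,male,third_molar,E,15.635305193532893
syn-000012,male,third_molar,C,8.475399516477259
syn-000013,male,third_molar,F,14.920234714361627
syn-000014,male,third_molar,C,7.064815006597401
syn-000015,male,third_molar,E,13.511668791723512
syn-000016,male,third_molar,H,20.658710766799526
syn-000017,male,third_molar,G,18.191998138320955
syn-000018,male,third_molar,E,15.35551313385766
syn-000019,male,third_molar,C,11.554895171158115
syn-000020,male,third_molar,C,9.888814759397425
syn-000021,male,third_molar,F,13.198157939299694
syn-000022,male,third_molar,C,10.892579596388213
syn-000023,male,third_molar,H,19.249409761767133
syn-000024,male,third_molar,C,9.984202840275548
syn-000025,male,third_molar,C,10.839430059573928
syn-000026,male,third_molar,G,18.300547810550015
syn-000027,male,third_molar,C,10.757114563649697
syn-000028,male,third_molar,C,10.75288017394681
syn-000029,male,third_molar,C,7.992344979222195
syn-000030,male,third_molar,E,13.540923393554774
syn-000031,male,third_molar,C,10.69887615916656
syn-000032,male,third_molar,H,19.44518853244089
syn-000033,male,third_molar,D,11.008456375596607
syn-000034,male,third_molar,F,17.832737043779524
syn-000035,male,third_molar,G,13.821428054731996
syn-000036,male,third_molar,E,13.552266657084523
syn-000037,male,third_molar,H,20.509022915926693
syn-000038,male,third_molar,F,19.575182680361625
syn-000039,male,third_molar,C,8.106480439365725
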