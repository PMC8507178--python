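event_id,timestamp,participant_id,smiles,parent_event_id,score
e01,2021-03-01T10:00:00+00:00,alice,C,,0
e02,2021-03-01T10:00:20+00:00,alice,CC,e01,34
e03,2021-03-01T10:00:45+00:00,alice,CCO,e02,138
e04,2021-03-01T10:00:50+00:00,bob,C,,0
e05,2021-03-01T10:01:10+00:00,bob,CN,e04,71
e06,2021-03-01T10:01:35+00:00,bob,CCN,e05,138
e07,2021-03-01T10:01:40+00:00,carol,c1ccccc1,,71
e08,2021-03-01T10:02:10+00:00,carol,Cc1ccccc1,e07,175
e09,2021-03-01T10:02:30+00:00,alice,CC(C)O,e03,61
e10,2021-03-01T10:05:00+00:00,alice,CC(C)=O,e09,61
e11,2021-03-01T10:05:20+00:00,bob,CNC,e05,31
e12,2021-03-01T10:05:40+00:00,carol,Cc1ccc(O)cc1,e08,256
e13,2021-03-01T10:06:00+00:00,alice,Cc1ccc(N)cc1,e12,256
e14,2021-03-01T10:06:20+00:00,alice,Cc1ccc(O)cc1,e13,256
e15,2021-03-01T10:06:40+00:00,bob,CN(C)C,e11,29
e16,2021-03-01T10:07:10+00:00,bob,CCc1ccc(O)cc1,e12,444
e17,2021-03-01T10:07:40+00:00,carol,Cc1ccccc1O,e12,289
e18,2021-03-01T10:07:55+00:00,carol,Oc1ccccc1,e17,237
e19,2021-03-01T10:08:20+00:00,alice,Cc1ccc(O)c(N)c1,e14,594
e20,2021-03-01T10:08:40+00:00,alice,Nc1ccc(O)cc1,e19,289
e21,2021-03-01T10:09:00+00:00,bob,CCc1ccc(O)cc1C,e16,385
e22,2021-03-01T10:10:00+00:00,bob,CCc1ccc(O)cc1,e21,444
e23,2021-03-01T10:10:40+00:00,carol,C,,0
e24,2021-03-01T10:10:55+00:00,carol,CS,e23,34
e25,2021-03-01T10:11:40+00:00,carol,CCS,e24,100
e26,2021-03-01T10:12:00+00:00,alice,Cc1ccc(O)c(C)c1,e20,378
e27,2021-03-01T10:13:10+00:00,bob,CCc1ccc(O)c(C)c1,e22,636
e28,2021-03-01T10:13:30+00:00,alice,CCc1ccc(O)c(N)c1,e16,1000
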