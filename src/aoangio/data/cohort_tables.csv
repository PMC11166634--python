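participant_id,group,age,sex,eye,grade,loops,dilated_saccular,microaneurysms
1,D,27,M,OD,mild_NPDR,1,1,1
1,D,27,M,OS,mild_NPDR,1,1,1
2,D,30,M,OD,very_mild_NPDR,1,0,1
2,D,30,M,OS,very_mild_NPDR,1,0,1
3,D,56,F,OD,mild_NPDR,0,0,1
3,D,56,F,OS,mild_NPDR,0,0,1
4,D,32,M,OD,mild_NPDR,1,1,1
5,D,63,F,OD,moderate_NPDR,0,0,1
5,D,63,F,OS,moderate_NPDR,0,0,1
6,D,29,F,OD,none,0,0,0
6,D,29,F,OS,very_mild_NPDR,0,0,0
7,D,33,M,OD,mild_NPDR,1,0,1
7,D,33,M,OS,very_mild_NPDR,1,0,1
8,D,31,F,OD,mild_NPDR,1,0,1
8,D,31,F,OS,very_mild_NPDR,1,0,1
9,D,22,M,OD,very_mild_NPDR,1,0,0
9,D,22,M,OS,very_mild_NPDR,1,0,0
10,D,49,M,OD,very_mild_NPDR,1,1,1
10,D,49,M,OS,very_mild_NPDR,1,1,1
11,D,24,F,OD,very_mild_NPDR,1,1,1
11,D,24,F,OS,very_mild_NPDR,1,1,1
12,H,29,F,OD,none,0,0,0
13,H,29,M,OD,none,0,0,0
14,H,15,M,OD,none,0,0,0
15,H,12,M,OD,none,0,0,0
16,H,28,F,OD,none,0,0,0
16,H,28,F,OS,none,0,0,0
17,H,27,F,OD,none,0,0,0
17,H,27,F,OS,none,0,0,0
18,H,40,M,OD,none,0,0,0
19,H,38,F,OS,none,0,0,0
20,H,59,M,OD,none,0,0,0
21,H,36,F,OD,none,0,0,0
21,H,36,F,OS,none,0,0,0
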