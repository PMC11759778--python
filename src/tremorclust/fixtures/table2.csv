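instance_id,updrs_score,predominant_cluster,correctly_classified
1,1,1,Yes
2,1,1,Yes
3,1,1,Yes
4,1,1,Yes
5,1,0,No
6,1,1,Yes
7,1,0,No
8,1,0,No
9,1,0,No
10,1,0,No
11,1,1,Yes
12,1,1,Yes
13,1,1,Yes
14,1,0,No
15,0,0,Yes
16,0,0,Yes
17,0,0,Yes
18,0,0,Yes
19,0,0,Yes
20,0,0,Yes
21,0,0,Yes
22,0,0,Yes
23,0,0,Yes
24,0,0,Yes
25,0,0,Yes
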