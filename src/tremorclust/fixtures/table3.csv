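instance_id,updrs_score,predominant_cluster,mapped_score,correctly_classified
1,2,3,2,Yes
2,3,3,2,No
3,2,3,2,Yes
4,2,3,2,Yes
5,1,1,1,Yes
6,3,2,3,Yes
7,2,1,1,No
8,1,1,1,Yes
9,1,1,1,Yes
10,2,1,1,No
11,3,3,2,No
12,1,3,2,No
13,1,2,3,No
14,1,1,1,Yes
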