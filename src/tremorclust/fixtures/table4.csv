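instance_id,binary_score,predominant_cluster,correctly_classified
1,1,2,No
2,2,1,No
3,1,1,Yes
4,1,1,Yes
5,1,1,Yes
6,2,2,Yes
7,1,1,Yes
8,1,1,Yes
9,1,1,Yes
10,1,1,Yes
11,2,2,Yes
12,1,2,No
13,1,2,No
14,1,1,Yes
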