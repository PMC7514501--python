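network	cluster_1	cluster_2	cluster_3	cluster_4	cluster_5	cluster_6
default	29	0	0	0	5	0
frontal-parietal	0	20	1	0	0	0
cingulo-opercular	1	3	23	3	0	2
sensorimotor	0	0	3	30	0	0
occipital	0	0	0	0	22	0
cerebellum	0	0	0	0	0	18
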