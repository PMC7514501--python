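network	cluster_1	cluster_2	cluster_3	cluster_4	cluster_5	cluster_6
default	25	2	0	0	6	1
frontal-parietal	0	20	1	0	0	0
cingulo-opercular	1	5	21	3	0	2
sensorimotor	0	0	1	32	0	0
occipital	0	0	0	0	22	0
cerebellum	0	2	0	0	2	14
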