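mtaqtl_id	traits	n_mtas	n_environments	chromosome	region_min	region_max
mtaq1A.1	GS	1	1	1A	2.7	2.7
mtaq1A.2	GS	5	1	1A	30.4	34.2
mtaq1B.1	TW	1	1	1B	0.0	0.0
mtaq1B.2	TW,YI	2	2	1B	20.6	27.2
mtaq2B.1	TW	1	1	2B	2.7	2.7
mtaq2B.2	TW	1	1	2B	42.2	42.2
mtaq2B.3	GPC,GS,TW	6	3	2B	133.4	146.3
mtaq2B.4	GPC	1	1	2B	169.5	169.5
mtaq2B.5	GS,TW,YI	3	3	2B	220.5	227.1
mtaq3A.1	GS,TW	5	4	3A	3.4	6.2
mtaq3B.1	YI	3	1	3B	47.8	47.9
mtaq3B.2	GPC,TW	3	2	3B	157.3	162.9
mtaq3B.3	GS,TW	2	2	3B	172	181.6
mtaq3B.4	YI	1	1	3B	216.3	216.3
mtaq4A.1	GPC,YI	2	1	4A	59.8	69.7
mtaq4A.2	YI	3	3	4A	136.7	136.7
mtaq4B.1	GPC,TW	8	3	4B	15.7	16.5
mtaq5A.1	GS	1	1	5A	83.6	83.6
mtaq5B.1	GS	2	2	5B	10.6	10.6
mtaq5B.2	TW	1	1	5B	88.8	88.8
mtaq5B.3	TW	3	1	5B	126.9	131.7
mtaq5B.4	GS	1	1	5B	145.4	145.4
mtaq5B.5	GPC	1	1	5B	172.4	172.4
mtaq5B.6	TW	1	1	5B	185.0	185.0
mtaq6A.1	YI	1	1	6A	0.0	0.0
mtaq6A.2	TW,YI	2	1	6A	137.1	137.1
mtaq6A.3	TW	1	1	6A	158.9	158.9
mtaq6B.1	YI	4	2	6B	4.4	14.7
mtaq6B.2	GS,YI	3	3	6B	23.6	24.7
mtaq7A.1	GPC,GS,TW	4	3	7A	6.1	8.2
mtaq7A.2	GPC	6	2	7A	63.2	63.2
mtaq7A.3	GPC,YI	2	2	7A	216.1	220.4
mtaq7B.1	GS	1	1	7B	18.0	18.0
mtaq7B.2	GS	2	2	7B	37.8	37.8
mtaq7B.3	GPC	3	3	7B	68.9	68.9
mtaq7B.4	GS,TW	3	2	7B	143	152.2
mtaq7B.5	YI	2	2	7B	184.8	189.0
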