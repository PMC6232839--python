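trait	marker	environment	chromosome	position_cM	neg_log10_p	r2
GPC	wPt-1140	2007	2B	133.4	3.63	0.09
GPC	wPt-8693	2009	2B	146.3	2.73	0.07
GPC	wPt-4223	2009	2B	169.5	2.59	0.06
GPC	wPt-2698	2007	3B	162.9	2.32	0.05
GPC	wPt-2698	across	3B	162.9	2.39	0.05
GPC	wPt-7355	2007	4A	59.8	3.00	0.08
GPC	wPt-6123	2008	4B	16.2	2.56	0.06
GPC	wPt-5497	2008	4B	16.3	2.56	0.06
GPC	tPt-5342	2008	4B	16.5	3.22	0.08
GPC	wPt-7400	2007	5B	172.4	2.34	0.05
GPC	wPt-6959	2007	7A	6.1	2.74	0.06
GPC	wPt-3883	2008	7A	63.2	2.61	0.06
GPC	wPt-3883	across	7A	63.2	2.76	0.06
GPC	wPt-7734	2008	7A	63.2	2.64	0.06
GPC	wPt-7734	across	7A	63.2	2.84	0.07
GPC	wPt-9796	2008	7A	63.2	2.64	0.06
GPC	wPt-9796	across	7A	63.2	2.77	0.06
GPC	wPt-4220	2008	7A	220.4	2.19	0.05
GPC	wPt-2737	2007	7B	68.9	3.12	0.08
GPC	wPt-2737	2008	7B	68.9	3.34	0.08
GPC	wPt-2737	across	7B	68.9	4.30	0.11
GS	wPt-6280	2009	1A.1	2.7	3.48	0.08
GS	wPt-1310	2008	1A.2	30.4	2.88	0.07
GS	wPt-6853	2008	1A.2	30.4	2.84	0.07
GS	wPt-1011	2008	1A.2	30.5	2.87	0.07
GS	wPt-5274	2008	1A.2	34.2	2.53	0.07
GS	wPt-6754	2008	1A.2	34.2	2.00	0.05
GS	wPt-1140	2007	2B	133.4	2.94	0.07
GS	wPt-6894	2008	2B	227.1	2.50	0.06
GS	wPt-6854	2008	3A.1	6.2	2.11	0.05
GS	wPt-11691	2009	3B	172	2.95	0.07
GS	tPt-0353	2008	5A	83.6	2.03	0.04
GS	rPt-6127	2008	5B	10.6	2.56	0.06
GS	rPt-6127	across	5B	10.6	2.61	0.06
GS	wPt-6880	2008	5B	145.4	2.49	0.06
GS	wPt-7954	2008	6B	23.6	2.06	0.05
GS	wPt-2056	2008	7A	8.2	2.11	0.05
GS	wPt-1853	2008	7B	18	3.07	0.08
GS	wPt-7653	2007	7B	37.8	2.73	0.06
GS	wPt-7653	across	7B	37.8	2.79	0.06
GS	wPt-4258	2008	7B	143	2.89	0.08
YI	wPt-2694	2007	1B	27.2	2.48	0.06
YI	wPt-2724	2007	2B	220.8	2.18	0.04
YI	wPt-8140	2007	3B	47.8	2.42	0.05
YI	wPt-1349	2007	3B	47.9	2.92	0.07
YI	wPt-8686	2007	3B	47.9	3.04	0.07
YI	wPt-2416	2009	3B	216.3	2.42	0.05
YI	wPt-0162	2007	4A	69.7	2.25	0.05
YI	wPt-3729	2007	4A	136.7	2.20	0.05
YI	wPt-3729	2008	4A	136.7	2.70	0.06
YI	wPt-3729	across	4A	136.7	2.61	0.06
YI	wPt-8443	2009	6A	0	2.39	0.05
YI	wPt-3247	2007	6A	137.1	2.32	0.05
YI	wPt-3774	2009	6B	4.4	2.60	0.06
YI	wPt-0245	2007	6B	5.1	2.56	0.06
YI	wPt-7662	2009	6B	6.2	2.76	0.06
YI	wPt-5673	2007	6B	14.7	2.45	0.05
YI	wPt-1437	2007	6B	24.7	2.52	0.06
YI	wPt-1437	2009	6B	24.7	3.22	0.08
YI	wPt-1429	2009	7A	216.1	2.85	0.06
YI	wPt-5228	2007	7B	184.8	2.24	0.05
YI	wPt-5138	across	7B	189	2.68	0.06
TW	wPt-2654	2008	1B	-0.9	2.84	0.06
TW	wPt-5562	across	1B	20.6	2.19	0.04
TW	wPt-1634	2007	2B	2.7	2.38	0.04
TW	wPt-7158	2008	2B	42.2	2.66	0.06
TW	wPt-1140	2007	2B	133.4	4.51	0.10
TW	wPt-1140	across	2B	133.4	3.60	0.08
TW	wPt-8569	across	2B	142.9	2.40	0.06
TW	wPt-7360	across	2B	220.5	2.17	0.04
TW	wPt-6204	2007	3A.1	3.4	3.45	0.07
TW	wPt-6204	2008	3A.1	3.4	3.41	0.08
TW	wPt-6204	2009	3A.1	3.4	3.14	0.07
TW	wPt-6204	across	3A.1	3.4	4.01	0.09
TW	wPt-8480	2007	3B	157.3	2.13	0.04
TW	wPt-2491	2008	3B	181.6	2.35	0.05
TW	wPt-8892	2007	4B	15.7	3.51	0.07
TW	wPt-8892	across	4B	15.7	2.53	0.05
TW	wPt-6123	2007	4B	16.2	2.26	0.04
TW	wPt-5497	2007	4B	16.3	2.26	0.04
TW	tPt-5342	2007	4B	16.5	2.16	0.04
TW	wPt-6022	2007	5B	88.8	2.43	0.05
TW	wPt-2707	2007	5B	126.9	3.68	0.08
TW	wPt-6191	2007	5B	126.9	3.60	0.07
TW	wPt-4577	2007	5B	131.7	3.70	0.08
TW	tPt-3714	2008	5B	185	2.55	0.06
TW	wPt-9000	2007	6A	137.1	2.39	0.05
TW	wPt-6995	2007	6A	158.9	2.20	0.04
TW	wPt-1441	2007	7A	8.1	3.01	0.06
TW	wPt-1441	across	7A	8.1	3.38	0.07
TW	wPt-5343	across	7B	152.2	2.54	0.05
TW	wPt-8615	across	7B	152.2	2.36	0.05
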