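chromosome	mqtl	position_cM	ci95_cM	left_marker	right_marker	n_qtl	traits
1A LG2	1	0.5	24.3	cfa2129	wPt-11558	2	YPC
1B	2	0.0	1.10	wPt-2654	wPt-8627	8	GS
1B	3	33.0	5.06	gwm18	ksum28	9	TW,GPC,YPC
1B	4	49.0	5.57	barc302	wmc419	7	GS,YPC,YI
1B	5	55.5	2.09	wmc419	wPt-9937	5	GS
1B	6	73.0	3.55	kbo-0425	wPt-0506	4	GS
1B	7	88.4	3.41	wPt-5011	rPt-7906	4	GPC,GS
2A LG1	8	71.0	0.81	gwm95	gwm372	11	GPC,YPC,YI
2B	9	32.0	4.86	wmc112	wPt-7932	5	TW,GPC
2B	10	57.1	6.93	gwm429	wPt-6477	2	GPC
2B	11	157.0	2.72	wPt-7305	wmc332	4	GPC
3B	12	10.4	5.09	cfb6018	gpw7774	4	TW,GPC
3B	13	73.6	6.94	CA499601b	wPt-10530	3	GPC
3B	14	92.9	11.8	wPt-5390	wmc1	3	TW,GS
3B	15	104.0	6.81	wPt-0446	barc164	2	GPC,GS
3B	16	152.0	4.70	wPt-7145	wPt-0384	5	GPC,YPC
3B	17	187.0	3.25	wPt-4401	wPt-6956	2	YI
4A	18	27.8	8.01	gwm610	Lp-A3	5	GPC,YPC
4A	19	95.1	9.42	wPt-1584	wPt-1701	2	GPC,YI
4A	20	126.0	10.6	wPt-3596	wPt-7354	3	GS,YI
4A	21	140.0	4.32	wmc723	wPt-9103	6	TW,GPC,YPC,YI
4B	22	10.6	5.26	gwm857	gwm368	2	TW,GPC
4B	23	31.0	5.92	wPt-1491	gwm781	2	GPC,GS
4B	24	62.7	12.1	wPt-8092	wPt-9625	2	GPC
5A	25	70.6	4.94	barc197	gwm639	3	GPC
5A	26	112.0	6.97	wPt-730410	barc142	3	GS
5A	27	159.0	5.89	gwm126	gwm291	2	TW
5B	28	38.4	10.3	wPt-1951	gwm213	2	GPC
5B	29	72.3	12.0	wmc415	kbo-0077	3	GPC,YPC,YI
5B	30	127.0	12.2	wPt-6014	barc140	2	GPC
6A	31	62.0	4.46	gwm132	gwm4675	4	YPC,YI
6A	32	90.7	2.03	gwm1150	wPt-2014	18	GS,YPC,YI
6A	33	118.0	5.59	gwm169	BE483091	2	YPC,YI
6B	34	100.0	4.22	wPt-6889	R18-370	2	TW,GPC
6B	35	112.0	4.55	gwm1682	850	2	GPC
6B	36	137.0	1.23	barc125a	wPt-5270	7	GS
7A	37	19.8	8.65	gwm1187	wmc168	3	GS
7A	38	88.7	4.38	wmc83	cfa2147	4	TW,GPC,YPC,YI
7A	39	113.0	2.11	gwm573	wPt-0321	2	GPC
7A	40	137.0	2.26	barc29	barc121	7	GS,YPC,YI
7A	41	214.0	0.11	BJ262177B	gwm1061	6	YPC,YI
7B	42	25.1	18.2	wmc323	wmc405	2	GPC,YI
7B	43	70.1	5.36	wPt-8273	gwm540a	6	TW,GPC,YPC,YI
7B	44	145.0	15.8	barc315	kbo-0372	2	GPC,YPC
7B	45	195.0	0.68	Psy-B1	wPt-7387	20	GPC,YPC,YI
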