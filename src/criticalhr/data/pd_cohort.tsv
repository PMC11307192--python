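id	sex	age_years	height_m	mass_kg	updrs2	updrs3	hy	mmse	tmt_a_s	tmt_b_s	tug_s	in_experiment2
1	M	64	1.69	74.0	8	25	2	29	37.72	73.22	5.22	1
2	M	76	1.65	58.0	14	31	2	27	82.60	146.08	7.03	0
3	F	78	1.45	44.4	7	23	2	27	53.35	210.05	6.88	0
4	M	68	1.65	72.0	12	48	2	24	67.84	153.29	4.96	1
5	F	67	1.57	69.8	16	33	2	26	37.21	143.98	6.22	1
6	F	77	1.40	48.2	13	52	2.5	21	227.64	153.29	7.60	0
7	M	83	1.61	70.0	6	20	2	30	76.63	173.19	7.37	0
8	F	78	1.46	48.8	10	24	2	28	22.92	205.67	8.27	1
9	M	72	1.60	65.0	10	39	2.5	26	67.84	153.29	11.36	0
10	M	82	1.67	81.6	13	31	2	28	79.64	155.09	6.39	1
11	M	67	1.74	97.0	14	33	2	30	45.00	109.94	6.12	0
12	F	66	1.58	49.0	9	27	2.5	25	27.22	61.91	5.42	1
13	M	61	1.74	87.0	6	20	1.5	29	66.29	168.38	7.30	1
14	F	66	1.58	49.0	8	29	2	29	76.00	153.29	5.81	0
15	M	74	1.67	86.0	14	24	2	27	49.76	238.69	7.57	1
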