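study_label	proband_disease	fdr_disease	relative_class	rr	log_rr	se	ci_low	ci_high	n_cases
Eaton 2007	SjD	SjD	first_degree	12.77	2.55	0.31	7.00	23.30	16
Eaton 2007	SjD	SjD	parent	14.79	2.69	0.31	8.10	27.00
Eaton 2007	SjD	SjD	sibling	16.59	2.81	0.713	4.10	67.10
Kuo 2015a	SjD	SjD	first_degree	12.37	2.52	0.13	9.54	16.05	105
Kuo 2015a	SjD	SjD	parent	12.46	2.52	0.15	9.34	16.62	47
Kuo 2015a	SjD	SjD	sibling	18.99	2.94	0.33	9.76	36.93	40
Thomsen 2020a	SjD	SjD	first_degree	8.64	2.16	0.077	7.44	10.05	177
Thomsen 2020a	SjD	SjD	parent	7.95	2.07	0.13	6.22	10.16	70
Thomsen 2020a	SjD	SjD	sibling	9.36	2.24	0.099	7.71	11.37	109
Anaya 2006	SjD	AD	first_degree	1.73	0.55	0.3	0.96	3.11	38
Priori 2007	SjD	AD	first_degree	5.14	1.64	0.5	1.93	13.67	33
Ben-Eli 2019	SjD	AD	first_degree	4.03	1.39	0.32	2.13	7.61	33
Thomsen 2020a	SjD	AD	first_degree	8.58	2.15	0.08	7.34	10.03	158
Hemminki 2009	SjD	RA	parent	2.12	0.75	0.33	1.11	4.03	11
Hemminki 2009	SjD	RA	sibling	2.25	0.81	0.57	0.74	6.84	8
Thomsen 2020a	SjD	RA	first_degree	1.77	0.57	0.049	1.61	1.95	409
Thomsen 2020a	SjD	SLE	first_degree	2.77	1.02	0.15	2.07	3.71	46
Thomsen 2020a	SjD	SSc	first_degree	2.06	0.72	0.26	1.23	3.46	15
Thomsen 2020a	SjD	IIM	first_degree	0.76	-0.27	0.48	0.30	1.94	5
Hemminki 2010	SjD	GD	parent	1.06	0.061	0.51	0.39	2.90	5
Hemminki 2010	SjD	GD	sibling	0.60	-0.50	1.10	0.07	5.24	2
Thomsen 2020b	SjD	GD	first_degree	1.22	0.21	0.095	1.02	1.48	109
Kuo 2015a	RA	SjD	first_degree	2.95	1.08	0.12	2.33	3.73	68
Thomsen 2020a	RA	SjD	first_degree	1.69	0.52	0.065	1.49	1.91	243
Bengtsson 2002	SLE	SjD	first_degree	3.22	1.17	0.78	0.70	14.69	4
Kuo 2015a	SLE	SjD	first_degree	5.87	1.77	0.093	4.89	7.05	117
Kuo 2015b	SLE	SjD	first_degree	6.25	1.83	0.099	5.15	7.58	109
Thomsen 2020a	SLE	SjD	first_degree	3.56	1.27	0.13	2.76	4.58	61
Kuo 2015a	SSc	SjD	first_degree	2.39	0.87	0.58	0.77	7.41	3
Kuo 2016	SSc	SjD	first_degree	2.77	1.02	0.50	1.04	7.35	4
Thomsen 2020a	SSc	SjD	first_degree	2.42	0.89	0.27	1.42	4.14	14
Ginn 1998	IIM	SjD	first_degree	0.21	-1.5606	1.48	0.011	3.88	1
Kuo 2015a	IIM	SjD	first_degree	0.71	-0.3425	1.00	0.10	5.07	1
Thomsen 2020a	IIM	SjD	first_degree	0.46	-0.7765	0.65	0.13	1.65	3
Nielsen 2008	MS	SjD	first_degree	1.70	0.5306	0.46	0.70	4.20	5
Kuo 2015a	MS	SjD	first_degree	3.38	1.22	0.50	1.26	9.05	4
Mescheriakova 2019	MS	SjD	first_degree	3.29	1.19	1.48	0.18	60.21	1
Kuo 2015a	T1D	SjD	first_degree	1.97	0.68	0.22	1.29	3.02	23
Kuo 2018	T1D	SjD	first_degree	1.66	0.51	0.16	1.21	2.26	30
Thomsen 2020b	GD	SjD	first_degree	1.42	0.35	0.086	1.20	1.68	141
Thomsen 2020b	HT	SjD	first_degree	1.42	0.35	0.093	1.18	1.70	114
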