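chrom	snp_n	chr_length_mbp	mean_distance_kb	n_cr_lean	n_cr_fat	mean_cr_length_kb_lean	mean_cr_length_kb_fat	coverage_cr_kb_lean	coverage_cr_kb_fat	max_cr_length_kb_lean	max_cr_length_kb_fat	cr_ratio_lean	cr_ratio_fat	cr_snps_lean	cr_snps_fat	max_cr_snps_lean	max_cr_snps_fat	cr_snp_frac_lean	cr_snp_frac_fat
1	7135	200.95	28.16	881	920	125.59	114.92	110644.43	105728.03	2288.64	2191.34	0.55	0.53	3906	3716	19	19	0.55	0.52
2	5290	154.46	29.20	639	695	149.62	108.91	95606.56	75690.16	2048.43	2042.96	0.62	0.49	3260	2628	19	19	0.62	0.50
3	4081	113.65	27.85	517	533	121.58	108.97	62855.68	58081.43	863.98	735.27	0.55	0.51	2301	2107	19	19	0.56	0.52
4	3313	94.16	28.42	411	428	137.96	108.07	56701.29	46255.07	2087.33	611.37	0.60	0.49	1992	1676	19	19	0.60	0.51
5	2170	62.23	28.68	260	266	138.85	105.39	36101.29	28034.75	823.62	816.35	0.58	0.45	1282	1032	19	19	0.59	0.48
6	1714	35.84	20.91	217	225	94.92	72.79	20598.01	16377.61	535.90	523.04	0.57	0.46	983	826	19	19	0.57	0.48
7	1769	38.17	21.58	197	232	111.15	86.03	21897.27	19958.16	621.29	2163.72	0.57	0.52	1048	899	19	19	0.59	0.51
8	1394	30.62	21.97	159	175	111.56	96.82	17738.07	16944.10	1914.74	1949.21	0.58	0.55	791	763	19	19	0.57	0.55
9	1168	24.02	20.57	159	153	78.35	75.92	12457.00	11615.65	413.33	403.29	0.52	0.48	613	557	19	17	0.52	0.48
10	1297	22.42	17.29	172	176	70.99	63.35	12210.13	11148.99	387.48	347.35	0.54	0.50	735	699	19	19	0.57	0.54
11	1196	21.87	18.29	128	156	124.72	83.15	15964.06	12971.74	886.96	1093.97	0.73	0.59	871	706	19	19	0.73	0.59
12	1324	20.45	15.44	169	184	71.34	51.16	12057.10	9412.86	352.96	369.92	0.59	0.46	809	633	19	19	0.61	0.48
13	1128	18.32	16.24	144	141	75.86	75.09	10924.53	10584.67	373.56	373.56	0.60	0.58	695	656	19	19	0.62	0.58
14	984	15.76	16.02	127	123	75.17	68.77	9546.48	8459.25	402.70	402.70	0.61	0.54	598	544	19	19	0.61	0.55
15	1010	12.93	12.80	123	133	58.20	50.28	7158.60	6687.12	407.05	407.05	0.55	0.52	567	541	19	19	0.56	0.54
16	12	0.17	13.87	3	1	41.85	67.25	125.54	67.25	64.36	67.25	0.74	0.40	9	3	4	3	0.75	0.25
17	844	10.61	12.57	112	108	59.07	43.89	6616.05	4740.59	242.32	236.98	0.62	0.45	523	394	19	19	0.62	0.47
18	845	10.89	12.88	112	121	48.74	45.96	5459.42	5561.31	317.30	317.30	0.50	0.51	431	431	12	19	0.51	0.51
19	804	9.89	12.31	117	110	36.01	48.41	4212.67	5325.00	406.27	371.08	0.43	0.54	353	421	14	19	0.44	0.52
20	1460	13.92	9.53	184	181	45.89	46.33	8442.96	8386.18	273.60	270.67	0.61	0.60	904	888	19	19	0.62	0.61
21	726	6.88	9.47	81	90	47.74	35.17	3867.13	3165.72	211.67	196.05	0.56	0.46	432	354	19	18	0.60	0.49
22	295	3.89	13.19	36	30	71.16	79.29	2561.59	2378.83	267.88	289.01	0.66	0.61	193	182	19	19	0.65	0.62
23	577	6.02	10.44	81	80	37.13	31.74	3007.73	2539.51	239.20	239.20	0.50	0.42	307	272	19	19	0.53	0.47
24	676	6.23	9.22	87	91	40.77	32.96	3546.91	2999.26	133.00	212.48	0.57	0.48	387	339	13	19	0.57	0.50
25	170	2.02	11.86	23	18	34.97	32.38	804.26	582.82	82.74	72.39	0.40	0.29	99	68	12	10	0.58	0.40
26	617	5.03	8.16	81	85	34.55	59.60	2798.60	2515.94	246.20	278.91	0.56	0.50	345	312	19	19	0.56	0.51
27	472	4.84	10.25	60	59	46.66	40.46	2799.62	2387.38	384.65	482.24	0.58	0.49	299	215	19	19	0.63	0.46
28	563	4.46	7.92	77	79	36.64	27.66	2820.93	2185.41	520.13	172.85	0.63	0.49	336	318	19	19	0.60	0.56
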