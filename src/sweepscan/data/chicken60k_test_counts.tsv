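chrom	tests_lean	p05_lean	p01_lean	tests_fat	p05_fat	p01_fat
1	2806	113	4	3063	138	12
2	2009	105	8	2271	104	3
3	1654	79	10	1705	74	8
4	1273	58	6	1371	66	5
5	844	34	3	883	36	4
6	699	25	2	757	31	2
7	638	29	2	770	31	5
8	464	16	1	574	33	2
9	516	20	1	564	19	1
10	540	23	2	582	27	1
11	397	15	1	534	20	2
12	503	14	0	619	20	1
13	447	19	3	474	22	1
14	379	14	0	418	16	1
15	329	12	1	420	18	2
17	350	16	0	348	14	2
18	354	12	2	432	13	2
19	334	12	1	338	13	0
20	561	28	3	566	19	0
21	255	6	0	304	11	0
22	105	5	1	85	2	0
23	258	11	0	245	12	1
24	287	9	0	308	12	2
25	46	1	0	36	1	0
26	231	11	0	253	4	0
27	181	8	0	184	7	0
28	217	5	0	242	14	0
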