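# Class2 (pleiotropic) common intervals: region in Mb (2 decimals), the data
# resource of the member clusters, the ear traits involved, and any known gene
# overlapping the region.
number	chrom	start_mb	end_mb	data_resource	traits	known_genes
1	1	0.00	0.61	QTN cluster	CD, KRN
2	1	1.96	2.11	QTN cluster	KRN, ED, CD
3	1	2.50	2.68	QTN cluster	CD, KRN
4	1	3.23	3.72	QTN cluster	CD, ED
5	1	26.40	26.90	QTN cluster	EL, KRN
6	1	28.45	28.48	QTN cluster	EL, CD, KRN
7	1	34.89	35.55	QTN cluster/QTL cluster	CD, EL
8	1	35.99	36.49	QTN cluster/QTL cluster	EL, ED
9	1	42.54	43.54	QTL cluster	EL, KNPR
10	1	44.18	44.90	QTL cluster	KWPE, ED
11	1	220.28	221.93	QTL cluster	KRN, CD
12	1	285.34	292.19	QTL cluster	KRN, KWPE
13	2	23.49	23.81	QTN cluster	CD, KRN
14	2	65.94	66.23	QTL cluster	KRN, KNPR	BA2
15	2	153.51	154.97	QTL cluster	EL, KRN
16	2	200.01	200.07	QTL cluster	KRN, ED
17	3	2.42	3.42	QTN cluster/QTL cluster	CD, KRN
18	3	3.19	3.28	QTL cluster	CD, KRN, EL
19	3	9.57	10.06	QTL cluster	EL, KRN
20	3	10.44	11.10	QTL cluster	KRN, EL
21	3	24.90	25.40	QTN cluster/QTL cluster	KRN, CD
22	3	154.92	155.42	QTN cluster/QTL cluster	KRN, ED
23	4	0.33	0.83	QTN cluster	CD, KRN
24	4	191.57	191.82	QTN cluster/QTL cluster	KRN, ED, EW
25	4	215.58	216.26	QTN cluster/QTL cluster	KRN, EL
26	4	244.05	244.61	QTN cluster/QTL cluster	KRN, ED
27	4	244.74	245.54	QTL cluster	KRN, ED
28	5	126.98	127.53	QTN cluster/QTL cluster	EL, KRN
29	5	137.90	138.57	QTL cluster	KNPR, EL
30	5	145.16	145.22	QTL cluster	CW, KRN, KWPE
31	5	164.69	166.10	QTL cluster	KRN, EL
32	5	196.69	197.81	QTL cluster	EL, KRN
33	5	213.77	214.96	QTL cluster	KRN, EL
34	5	216.13	216.72	QTN cluster/QTL cluster	EL, CD
35	8	121.24	121.27	QTN cluster/QTL cluster	KRN, CD, EL
36	8	167.11	167.61	QTN cluster/QTL cluster	KRN, ED
37	9	10.90	12.21	QTL cluster	ED, KRN
38	9	13.09	14.78	QTL cluster	ED, KRN
39	10	94.76	98.77	QTL cluster	EW, KNPR	ACO2
40	10	148.31	148.42	QTN cluster/QTL cluster	KRN, EL
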