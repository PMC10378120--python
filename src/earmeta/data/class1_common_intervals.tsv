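# Class1 common intervals for KRN: QTL-cluster x QTN-cluster overlaps, with
# printed Start/End in Mb (2 decimals) and the known cloned gene per row.
# Row 11's chromosome cell is empty in the printed source; it is recorded here
# as chromosome 5 because rows 10-15 form the Chr5 series and its interval
# continues that series (provenance note, not a silent fix).
number	chrom	qtl_start_mb	qtl_end_mb	qtn_start_mb	qtn_end_mb	known_genes
1	1	293.44	304.60	297.63	298.13
2	1	293.44	304.60	299.78	300.29	IDS1/KRN1
3	2	5.47	5.85	4.84	5.83
4	2	19.86	26.25	21.48	22.02
5	2	19.86	26.25	23.49	24.19
6	3	14.89	26.40	17.27	18.08
7	3	226.09	228.09	225.85	226.54
8	4	195.32	239.24	204.74	205.67	RKN4, UB3
9	4	195.32	239.24	205.76	206.52	RKN4, UB3
10	5	20.41	23.71	22.80	23.30
11	5	36.01	51.50	35.58	36.47
12	5	36.01	51.50	41.07	41.62
13	5	36.01	51.50	44.21	44.71
14	5	60.99	67.09	65.79	66.29	TD1
15	5	141.98	184.11	146.17	146.67
16	7	11.68	12.63	12.00	12.62
17	7	21.96	45.32	41.96	42.46	SID1
18	8	112.72	122.82	113.29	113.98
19	9	27.76	29.76	28.29	29.03
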