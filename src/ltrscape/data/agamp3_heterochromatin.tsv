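region	ltr_bp	pct_of_region	insertions	per_mb	proviral	solo	pct_proviral_fragmented	mean_div	sd_div	in_clusters	genes_per_mb	size_mb
2L_H	280640	8.93	70	22.28	50	19	72.0	2.54	2.65	39	13.05	3.14
2L_PH	232291	9.55	56	23.03	42	13	75.0	2.41	2.53	32	12.34	2.43
2L_DIH	48349	6.81	14	19.72	8	6	57.1	3.0	3.15	7	15.49	0.71
2R_H	147873	5.77	32	12.5	25	7	47.1	2.43	2.05	13	12.11	2.56
3L_H	198661	7.69	53	20.53	32	21	69.6	2.50	2.32	34	16.65	2.59
3L_PH	145321	8.01	36	19.83	22	14	80.0	2.46	2.25	26	18.18	1.82
3L_DIH	53340	6.95	17	22.16	10	7	50.0	2.58	2.52	8	13.04	0.77
3R_H	108438	2.77	50	12.79	20	30	75.0	2.40	2.68	14	14.83	3.91
3R_PH	63439	6.11	17	16.36	13	4	81.8	1.97	2.30	5	22.14	1.04
3R_CIH	44999	1.56	33	11.49	7	26	60.0	2.76	2.99	9	12.18	2.87
X_H	357360	8.15	85	19.39	54	29	63.6	2.46	2.98	35	12.78	4.38
Total_H	1092972	6.59	290	17.49	182	106	66.2	2.47	2.62	135	13.81	16.58
Total_PH	946284	7.74	226	18.48	157	67	68.1	2.40	2.57	111	14.15	12.23
Total_DIH	101689	6.89	31	20.99	18	13	53.3	2.79	2.80	15	14.22	1.48
Total_CIH	44999	1.56	33	11.49	7	26	60.0	2.76	2.99	9	12.18	2.87
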