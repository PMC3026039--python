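region	ltr_bp	pct_of_region	insertions	per_mb	proviral	solo	pct_proviral_fragmented	mean_div	sd_div	in_clusters	genes_per_mb	size_mb
2L_E	270776	0.59	97	2.11	56	40	30.6	2.12	2.79	25	65.26	45.90
2L_PE	49198	1.64	14	4.66	9	5	50.0	2.25	2.86	0	69.00	3.00
2L_NPE	221578	0.52	83	1.93	47	35	26.2	2.09	2.81	25	65.01	42.90
2R_E	406752	0.69	155	2.63	92	60	42.1	2.07	2.74	35	64.00	58.97
2R_PE	90482	3.02	28	9.33	19	8	66.7	3.04	3.58	19	73.33	3.00
2R_NPE	316270	0.57	127	2.27	73	52	36.9	1.91	2.58	16	63.50	55.97
3L_E	229275	0.59	102	2.60	47	48	38.1	2.08	2.62	22	53.18	39.17
3L_PE	7175	0.24	10	3.33	4	4	33.3	1.79	1.79	3	57.33	3.00
3L_NPE	222100	0.61	92	2.54	43	44	38.5	2.10	2.70	19	52.84	36.17
3R_E	233438	0.48	105	2.14	45	58	30.0	1.77	2.57	10	50.69	40.06
3R_PE	34463	1.15	23	7.66	7	16	57.1	2.42	2.48	4	34.00	3.00
3R_NPE	199025	0.43	82	1.78	38	42	24.2	1.62	2.59	6	51.78	46.06
X_E	130369	0.65	53	2.66	23	30	43.8	1.72	2.26	19	51.89	19.93
X_PE	53285	1.78	15	5.00	8	7	57.1	1.29	1.75	8	48.00	3.00
X_NPE	77084	0.46	38	2.24	15	23	33.3	1.94	2.49	11	52.57	16.93
Total_E	1270660	0.60	512	2.40	263	236	36.8	1.99	2.65	111	58.09	213.03
Total_PE	234603	1.56	90	6.00	47	40	56.8	2.27	2.71	34	56.33	15.00
Total_NPE	1036057	0.52	422	2.13	216	196	32.4	1.94	2.64	77	58.22	198.03
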