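region	ltr_bp	pct_of_region	insertions	per_mb	in_clusters	size_mb
2L	553250	1.12	169	3.42	64	49.36
2R	554625	0.90	187	3.04	48	61.55
3L	428819	1.02	156	3.72	56	41.96
3R	342671	0.64	156	2.93	24	53.20
X	487729	2.00	138	5.67	54	24.40
Total	2367094	1.03	806	3.50	246	230.47
Total_UNK	3462	NA	4	NA	2	0.86
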