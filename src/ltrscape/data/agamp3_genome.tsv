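quantity	value
total_ltr_bp	3197007
assembly_bp	273093681
n_copies	1045
n_families	73
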