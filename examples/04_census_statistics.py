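"""Recompute the published AgamP3 census statistics from its summary tables.

The packaged per-region tables (counts, condition splits, sizes) are the
inputs; every statistic below is derived from them at run time.
"""

from ltrscape import headline_statistics

s = headline_statistics()

print(f"X-chromosome overrepresentation: chi2 = {s['chisq_x_overrepresentation']:.2f}")
print("  (X holds 17% of insertions on 10% of the assembly; expectation "
      "proportional to arm length, df=1)")
print(f"short-arm (2L+3L) excess:        chi2 = {s['chisq_short_arm_excess']:.2f}")
print(f"PE enrichment in euchromatin:    chi2 = {s['chisq_pe_enrichment']:.2f}")
print(f"proviral:solo, PH vs NPE:        chi2 = {s['chisq_condition_ph_vs_npe']:.2f}")
print("  (2x2 Pearson without continuity correction: proviral copies are "
      "retained where recombination is low)")
print(f"density in PH:     {s['density_ph_per_mb']:.2f} insertions/Mb")
print(f"genome-wide:       {s['density_genome_per_mb']:.2f} insertions/Mb")
print(f"heterochromatin holds {s['het_bp_share_pct']:.0f}% of Ty3/gypsy bp "
      "in 7.2% of the genome")
print(f"Ty3/gypsy fraction of the assembly: {s['genome_fraction_pct']:.2f}%")
print(f"heterochromatin vs NPE divergence: t = {s['t_het_vs_npe_divergence']:.2f}, "
      f"p = {s['p_het_vs_npe_divergence']:.4f} "
      "(older copies persist in heterochromatin)")
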