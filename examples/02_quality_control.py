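"""QC-filter a simulated panel with the four standard chip filters.

Removes SNPs that are non-autosomal, have call rate <= 95%, minor allele
frequency <= 0.05, or an exact Hardy-Weinberg p-value below 1e-4 (pooled
across breeds), and prints the per-criterion accounting.
"""

from breedscan import QCConfig, SimConfig, apply_qc, simulate_panel

panel, _ = simulate_panel(SimConfig(seed=1))
filtered, report = apply_qc(panel, QCConfig())

print(f"input SNPs: {report.n_input}")
for criterion, n in report.removed.items():
    print(f"  removed by {criterion}: {n}")
print(f"retained: {report.n_retained} "
      f"(accounting reconciles: {report.reconciles()})")
# Each removal count is taken on the survivors of the previous filter, so
# the removals plus the retained SNPs sum exactly to the input count.
print(report.per_snp[~report.per_snp.passed].head(5).to_string(index=False))
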