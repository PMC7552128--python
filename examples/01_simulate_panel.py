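"""Simulate a four-breed SNP panel with planted divergent loci.

Draws a 10,000-SNP chip-style panel for four breeds (17/17/16/16 animals)
under the Balding-Nichols model, with 20 loci given strongly elevated
divergence (F = 0.5) in the first, "highland", breed, and writes it as
PLINK text plus a truth table.
"""

from breedscan import SimConfig, simulate_panel, write_plink_text
from breedscan.simulate import write_truth_table

config = SimConfig(seed=1)
panel, truth = simulate_panel(config)

print(f"panel: {panel.n_samples} samples x {panel.n_snps} SNPs")
print(f"breeds: {panel.breed_names}")
print(f"planted loci: {truth['selected'].sum()} "
      f"(focal breed {panel.breed_names[config.focal_pop]})")
print("first planted locus:")
print(truth[truth["selected"]].head(1).to_string(index=False))

write_plink_text(panel, "scratch_panel")
write_truth_table(truth, "scratch_truth.tsv")
print("wrote scratch_panel.ped/.map and scratch_truth.tsv")
# The freq_* columns are the per-breed frequencies genotypes were drawn
# from: at planted loci the focal breed's frequency is far from the others.
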