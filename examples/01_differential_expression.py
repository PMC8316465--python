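"""Two-group NB differential expression on a small simulated cohort.

Generates a 4-control vs 5-case count matrix with planted fold changes,
runs the NB Wald test and applies the FDR <= 0.01, |log2FC| >= 1.5 calls.
"""

from epilink import classify_de, test_two_group
from epilink.simulate import SimulationConfig, simulate_study

bundle = simulate_study(SimulationConfig(seed=0, n_genes=500, genome_length=8_000_000))
groups = [bundle.sample_groups[s] for s in bundle.counts.columns]

de = classify_de(test_two_group(bundle.counts, groups, control="control"))
up, down = (de["call"] == "up").sum(), (de["call"] == "down").sum()
truth_up = (bundle.truth.gene_status == 1).sum()
truth_down = (bundle.truth.gene_status == -1).sum()

print(de[de["call"] != "ns"].head())
print(f"called {up} up / {down} down; planted {truth_up} up / {truth_down} down")
print("Each row: mean expression, log2 fold change (case vs control), Wald SE, p, BH FDR.")
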