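"""Call allelic expression imbalance (AEI) gene by gene on simulated counts.

Plants true allelic folds of 3.0 and 2.2 in two genes (all others balanced),
pushes the counts through the depth filter, 100-bp window merging and
gene-level combination, and prints the permissive and stringent calls.
"""

from aeikit import SimulationConfig, filter_sites, simulate_counts
from aeikit.io import frame_to_counts
from aeikit.pipeline import aei_table

cfg = SimulationConfig(
    n_genes=12, snps_per_gene=(2, 4), depth=80, bias_beta=0.0, n_samples=1,
    seed=5, true_ratio={"GENE003": 3.0, "GENE007": 2.2},
)
frame, truth = simulate_counts(cfg)
counts = filter_sites(frame_to_counts(frame))
print(f"{len(counts)}/{len(frame)} sites pass the >=3-reads-per-allele, "
      f">=5%-minor-allele filter")

table = aei_table(counts)
cols = ["gene", "n_obs", "mean_folded", "sd_folded",
        "call_permissive", "call_stringent_2sd"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))

called = table[table.call_permissive].gene.tolist()
print(f"\npermissive AEI calls (mean fold >= 2, >= 2 observations): {called}")
print("genes with planted imbalance: ['GENE003', 'GENE007']")
print("GENE003 shows a ~3-fold ratio but its SNPs fell inside one 100-bp "
      "window, leaving a single merged observation — the >=2-observation "
      "rule withholds the call rather than trust a lone SNP")
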