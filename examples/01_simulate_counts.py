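"""Generate a synthetic gene-edited iPSC RNA-seq experiment.

Builds the canonical 4-line design (3 stock replicates + 3 edited sublines
per line), draws negative-binomial counts with line, batch and editing
structure, and prints the ground truth that downstream benchmarks score
against.  Reduced gene count keeps the example instant; drop ``n_genes``
to use the full default transcriptome size.
"""

import numpy as np

import editbench as eb

design = eb.make_design(n_lines=4, n_stock=3, n_edited=3)
params = eb.SimulationParams(n_genes=2000, libsize_logmean=np.log(5e5), seed=42)
counts, truth = eb.simulate_counts(design, params)

print(design.head(6).to_string(index=False))
print(f"\ncounts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"median library {int(counts.sum().median()):,} reads")

affected = truth[truth.affected]
print(f"{len(affected)} genes carry a true editing effect; "
      f"HPRT1-like log2FC = {affected.set_index('gene_id').loc['HPRT1', 'true_log2fc']:.1f}")
# the HPRT1-like knockdown is visible directly in the raw counts:
edited = design.loc[design.status == "edited", "sample_id"]
stock = design.loc[design.status == "stock", "sample_id"]
ratio = counts.loc["HPRT1", edited].mean() / counts.loc["HPRT1", stock].mean()
print(f"observed edited/stock count ratio for HPRT1: {ratio:.3f} (expected 2^-3 = 0.125)")
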