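"""How well do per-line DE results agree across stock lines?

Analyses each line separately with the NB exact test, then reports the
overlap of significant sets, the Pearson correlation of fold changes, and
direction-consistency classes.  With shared true effects plus line-specific
noise, the overlap is far smaller than any single line's list -- the
phenomenon that motivates multi-line designs.
"""

import numpy as np

import editbench as eb

design = eb.make_design()
counts, truth = eb.simulate_counts(
    design, eb.SimulationParams(n_genes=2000, libsize_logmean=np.log(5e5), seed=19)
)

results = {}
for line in sorted(design.line.unique()):
    sub = design[design.line == line]
    results[line] = eb.two_group_de(
        counts[sub.sample_id], sub.loc[sub.status == "edited", "sample_id"], engine="exact"
    )

summary = eb.deg_overlap(results, q_threshold=0.05)
print("significant genes per line:", summary.set_sizes)
print("common to all four lines:", summary.common_to_all())

r, p = eb.foldchange_correlation(results, gene_selection="union-significant")
print("\nPearson r of log2 fold changes (union of significant genes):")
print(r.round(2).to_string())

classes = eb.direction_consistency(results, q_threshold=0.05)
print("\ndirection classes:")
print(classes.direction_class.value_counts().to_string())
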