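"""TMM normalization, log2-CPM, and sample-relatedness PCA.

TMM factors correct for library composition; the PCA of centered and scaled
log2-CPM shows how samples group by stock line (line-to-line differences
dominate the editing effect, which is the study's central observation).
"""

import numpy as np

import editbench as eb

design = eb.make_design()
counts, _ = eb.simulate_counts(
    design, eb.SimulationParams(n_genes=2000, libsize_logmean=np.log(5e5), seed=7)
)

factors = eb.tmm_factors(counts)
print("TMM factors (geometric mean 1):")
print(factors.factors.round(3).to_string())

keep = eb.filter_low_expression(counts, design, min_cpm=0.5)
logcpm = eb.cpm(counts.loc[keep], factors, log=True)
print(f"\nexpression filter keeps {int(keep.sum())}/{len(keep)} genes")

pca = eb.pca_samples(logcpm, center=True, scale=True)
print("\nvariance explained by PC1-PC3:", np.round(pca.variance_explained[:3], 3))
scores = pca.scores.join(design.set_index("sample_id")[["line", "status"]])
print("\nmean PC1 coordinate per line (lines separate along the top components):")
print(scores.groupby("line")["PC1"].mean().round(2).to_string())
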