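"""Score single-line DE results against an aggregate 'common standard'.

The joint, line-adjusted analysis of all lines defines a reference gene
list; each line's own significant list is then split into true positives
(inside the reference) and false positives (outside).  The percentages
mirror the performance-table semantics used for multi-line evaluations:
TP% is of the reference size, FP% of the line's total calls.
"""

import dataclasses

import numpy as np
import pandas as pd

import editbench as eb

design = eb.make_design()
counts, _ = eb.simulate_counts(
    design, eb.SimulationParams(n_genes=2000, libsize_logmean=np.log(5e5), seed=31)
)

reference = eb.build_aggregate_reference(counts, design, engine="glm", q_threshold=0.05)
print(f"aggregate line-adjusted reference: {len(reference)} genes\n")

rows = []
for line in sorted(design.line.unique()):
    sub = design[design.line == line]
    res = eb.two_group_de(
        counts[sub.sample_id], sub.loc[sub.status == "edited", "sample_id"], engine="exact"
    )
    ev = eb.evaluate_against_reference(res, reference, q_threshold=0.05, line=line)
    rows.append(dataclasses.asdict(ev))

table = pd.DataFrame(rows)[
    ["line", "total_significant", "tp", "tp_pct", "fp", "fp_pct"]
]
print(table.to_string(index=False))
print("\ntp_pct = 100*tp/reference size; fp_pct = 100*fp/total significant")
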