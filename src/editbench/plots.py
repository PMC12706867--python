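"""Minimal matplotlib renderings of benchmark and variance-partition output."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_performance", "plot_variance_fractions"]


def plot_performance(perf, ax=None):
    """Sensitivity and specificity per fold-change level, one panel."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = perf.table.sort_values("level")
    x = np.log2(t["level"])
    ax.plot(x, t["sensitivity"], "o-", label="sensitivity")
    ax.plot(x, t["specificity"], "s-", label="specificity")
    ax.set_xlabel("log2 fold-change level")
    ax.set_ylabel("rate")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"{perf.engine}: spike-in detection")
    return ax


def plot_variance_fractions(vp, factors=None, ax=None):
    """Violin summary of per-gene variance fractions by factor."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cols = factors or [c for c in vp.columns if c != "gene_id"]
    ax.violinplot([vp[c].to_numpy() for c in cols], showmedians=True)
    ax.set_xticks(range(1, len(cols) + 1), cols)
    ax.set_ylabel("variance fraction")
    ax.set_ylim(0, 1)
    return ax
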