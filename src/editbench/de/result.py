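"""The common tabular result emitted by every DE engine."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .multtest import bh_adjust

__all__ = ["make_de_result", "significant_genes"]

RESULT_COLUMNS = ["gene_id", "log2fc", "p", "q", "mean_abundance", "method"]


def make_de_result(
    gene_ids,
    log2fc,
    p,
    mean_abundance,
    method: str,
    contrast: str = "",
) -> pd.DataFrame:
    """Assemble a DE result table in input gene order, with BH q-values."""
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids, dtype=object),
            "log2fc": np.asarray(log2fc, dtype=float),
            "p": np.asarray(p, dtype=float),
            "q": bh_adjust(p),
            "mean_abundance": np.asarray(mean_abundance, dtype=float),
            "method": method,
        }
    )
    df.attrs["contrast"] = contrast
    return df


def significant_genes(result: pd.DataFrame, q_threshold: float = 0.05) -> set[str]:
    """Genes called at ``q < q_threshold`` (NaN q never significant)."""
    mask = result["q"] < q_threshold
    return set(result.loc[mask.fillna(False), "gene_id"])
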