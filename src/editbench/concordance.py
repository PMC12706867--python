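"""Agreement of DE results across stock lines.

Three views of cross-line concordance: overlap of significant gene sets
(full Venn semantics over every non-empty subset of lines), Pearson
correlation of log2 fold-change vectors, and per-gene direction-consistency
classes that name the dissenting line when one line disagrees with the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._errors import DesignError, ParameterError
from .de.result import significant_genes

__all__ = [
    "ConcordanceSummary",
    "deg_overlap",
    "foldchange_correlation",
    "direction_consistency",
]


def _as_named_results(results) -> dict[str, pd.DataFrame]:
    if isinstance(results, Mapping):
        return dict(results)
    return {f"set{i + 1}": r for i, r in enumerate(results)}


def _check_universe(named: dict[str, pd.DataFrame]) -> pd.Index:
    names = list(named)
    universe = pd.Index(named[names[0]]["gene_id"])
    for nm in names[1:]:
        other = pd.Index(named[nm]["gene_id"])
        if len(universe.symmetric_difference(other)) != 0:
            raise DesignError(
                f"gene universes differ between {names[0]!r} and {nm!r}; "
                "align the inputs explicitly rather than silently intersecting"
            )
    return universe


@dataclass
class ConcordanceSummary:
    """Per-subset overlap counts of significant gene sets."""

    names: list[str]
    set_sizes: dict[str, int]
    #: genes significant in every member of the subset (>= semantics)
    intersection_counts: dict[frozenset, int]
    #: genes significant in exactly the subset's members (Venn regions)
    exclusive_counts: dict[frozenset, int]
    q_threshold: float

    def common_to_all(self) -> int:
        return self.intersection_counts[frozenset(self.names)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.intersection_counts, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {
                    "subset": "+".join(sorted(subset)),
                    "n_lines": len(subset),
                    "intersection": self.intersection_counts[subset],
                    "exclusive": self.exclusive_counts[subset],
                }
            )
        return pd.DataFrame(rows)


def deg_overlap(results, q_threshold: float = 0.05) -> ConcordanceSummary:
    """Overlap structure of significant genes across result sets.

    ``results`` is a mapping name -> DE result table (or a sequence, named
    ``set1..setk``), all on the same gene universe.  For every non-empty
    subset of lines both the plain intersection count and the exclusive
    (Venn-region) count are reported.
    """
    named = _as_named_results(results)
    if len(named) < 2:
        raise ParameterError("need at least two result sets")
    _check_universe(named)
    sets = {nm: significant_genes(df, q_threshold) for nm, df in named.items()}
    names = list(named)
    inter: dict[frozenset, int] = {}
    excl: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            fs = frozenset(subset)
            inside = set.intersection(*(sets[nm] for nm in subset))
            inter[fs] = len(inside)
            outside = set().union(*(sets[nm] for nm in names if nm not in fs)) if len(fs) < len(names) else set()
            excl[fs] = len(inside - outside)
    return ConcordanceSummary(
        names=names,
        set_sizes={nm: len(s) for nm, s in sets.items()},
        intersection_counts=inter,
        exclusive_counts=excl,
        q_threshold=q_threshold,
    )


def foldchange_correlation(
    results,
    gene_selection: str = "union-significant",
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of log2 fold changes across result sets.

    ``gene_selection`` is ``"union-significant"`` (genes differentially
    expressed in any line at ``q < q_threshold``) or ``"all"``.  Returns
    ``(r, p)`` matrices; pairs involving a zero-variance vector are NaN.
    """
    named = _as_named_results(results)
    if len(named) < 2:
        raise ParameterError("need at least two result sets")
    universe = _check_universe(named)
    if gene_selection == "all":
        genes = list(universe)
    elif gene_selection == "union-significant":
        union: set[str] = set()
        for df in named.values():
            union |= significant_genes(df, q_threshold)
        genes = [g for g in universe if g in union]
    else:
        raise ParameterError(f"unknown gene_selection {gene_selection!r}")
    if len(genes) < 3:
        raise ParameterError("need at least three genes for correlations")

    lfc = pd.DataFrame(
        {nm: df.set_index("gene_id")["log2fc"].reindex(genes) for nm, df in named.items()}
    )
    names = list(named)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for a, b in combinations(names, 2):
        xa, xb = lfc[a].to_numpy(), lfc[b].to_numpy()
        if np.std(xa) == 0 or np.std(xb) == 0:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        rr, pp = pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def direction_consistency(results, q_threshold: float = 0.05) -> pd.DataFrame:
    """Classify sign agreement across lines for genes significant anywhere.

    For each gene significant in at least one result set, the signs of its
    nonzero fold changes across all sets are compared: ``consistent-all``
    (all agree), ``consistent-majority-with-dissent(<line>)`` (exactly one
    line disagrees with the rest), else ``mixed``.  Exact-zero fold changes
    are direction-neutral and excluded from the vote.
    """
    named = _as_named_results(results)
    if len(named) < 2:
        raise ParameterError("need at least two result sets")
    _check_universe(named)
    union: set[str] = set()
    for df in named.values():
        union |= significant_genes(df, q_threshold)
    lfc = pd.DataFrame({nm: df.set_index("gene_id")["log2fc"] for nm, df in named.items()})

    rows = []
    for g in sorted(union):
        signs = {nm: np.sign(lfc.loc[g, nm]) for nm in named if lfc.loc[g, nm] != 0}
        vals = list(signs.values())
        if not vals:
            cls, dissent = "mixed", ""
        elif all(v == vals[0] for v in vals):
            cls, dissent = "consistent-all", ""
        else:
            pos = [nm for nm, v in signs.items() if v > 0]
            neg = [nm for nm, v in signs.items() if v < 0]
            if len(pos) == 1 and len(neg) >= 2:
                cls, dissent = f"consistent-majority-with-dissent({pos[0]})", pos[0]
            elif len(neg) == 1 and len(pos) >= 2:
                cls, dissent = f"consistent-majority-with-dissent({neg[0]})", neg[0]
            else:
                cls, dissent = "mixed", ""
        rows.append({"gene_id": g, "direction_class": cls, "dissenting_line": dissent})
    return pd.DataFrame(rows, columns=["gene_id", "direction_class", "dissenting_line"])
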