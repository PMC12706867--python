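"""End-to-end DE pipelines: normalize, estimate, test.

Thin orchestration over :mod:`editbench.normalize` and :mod:`editbench.de`
used by the benchmark, the CLI, and the examples.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from ._errors import DesignError
from .de import (
    consensus_block_correlation,
    design_matrix,
    estimate_dispersions,
    nb_exact_test,
    nb_glm_lrt,
    precision_weights,
    two_group_design,
    weighted_moderated_t,
)
from .normalize import tmm_factors

__all__ = ["two_group_de", "edit_contrast_de", "ENGINES"]

ENGINES = ("exact", "glm", "wmt")


def two_group_de(
    counts: pd.DataFrame,
    group1: Sequence[str],
    engine: str = "exact",
    prior_n: float = 10.0,
) -> pd.DataFrame:
    """TMM-normalize and test ``group1`` against the remaining samples.

    The reported fold change is group1 over the rest.  Engines: ``exact``
    (NB exact test), ``glm`` (NB GLM-LRT), ``wmt`` (precision-weighted
    moderated t).
    """
    group1 = list(group1)
    rest = [s for s in counts.columns if s not in set(group1)]
    if not group1 or not rest:
        raise DesignError("both groups must be non-empty")
    factors = tmm_factors(counts)
    design = two_group_design(counts.columns, group1)
    if engine == "exact":
        disp = estimate_dispersions(counts, design, factors, prior_n=prior_n)
        labels = ["g1" if s in set(group1) else "g0" for s in counts.columns]
        return nb_exact_test(counts, labels, disp, factors, pair=("g0", "g1"))
    if engine == "glm":
        disp = estimate_dispersions(counts, design, factors, prior_n=prior_n)
        return nb_glm_lrt(counts, design, disp, factors=factors)
    if engine == "wmt":
        logcpm, weights = precision_weights(counts, design, factors=factors)
        return weighted_moderated_t(logcpm, weights, design)
    raise DesignError(f"unknown engine {engine!r}; choose from {ENGINES}")


def edit_contrast_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    engine: str = "glm",
    adjust_line: bool = True,
    prior_n: float = 10.0,
) -> pd.DataFrame:
    """Edited-vs-stock contrast over a multi-line sample sheet.

    With ``adjust_line`` the GLM includes stock-line indicator covariates
    and the moderated-t engine uses a consensus within-line block
    correlation, isolating editing effects from baseline line differences.
    """
    samples = (samples.set_index("sample_id").loc[list(counts.columns)]
               .rename_axis("sample_id").reset_index())
    factors = tmm_factors(counts)
    if engine == "glm":
        fac = ("line", "status") if adjust_line else ("status",)
        design = design_matrix(samples, factors=fac, coef="status")
        disp = estimate_dispersions(counts, design, factors, prior_n=prior_n)
        return nb_glm_lrt(counts, design, disp, factors=factors)
    if engine == "wmt":
        design = design_matrix(samples, factors=("status",), coef="status")
        logcpm, weights = precision_weights(counts, design, factors=factors)
        if adjust_line:
            rho = consensus_block_correlation(logcpm, design, samples["line"])
            return weighted_moderated_t(
                logcpm, weights, design, block=samples["line"], rho=rho
            )
        return weighted_moderated_t(logcpm, weights, design)
    if engine == "exact":
        if adjust_line:
            raise DesignError("the exact test cannot adjust for line; use glm or wmt")
        design = design_matrix(samples, factors=("status",), coef="status")
        disp = estimate_dispersions(counts, design, factors, prior_n=prior_n)
        return nb_exact_test(counts, samples["status"], disp, factors)
    raise DesignError(f"unknown engine {engine!r}; choose from {ENGINES}")
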