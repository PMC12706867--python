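"""Per-gene decomposition of expression variance into design factors.

For each gene, the model  y_s = mu + sum_f a_f(level_f(s)) + e_s  with
independent random factor effects implies, for any sample pair (i, j),

    E[(y_i - y_j)^2] / 2 = sigma_e^2 + sum_f sigma_f^2 * 1[f_i != f_j].

Regressing the observed squared half-differences of all sample pairs on the
level-disagreement indicators (non-negative least squares, which doubles as
the truncation of negative components at zero) yields method-of-moments
variance components that handle unbalanced and crossed designs without
per-gene iterative fitting.  Fractions are the components divided by their
sum, so they are non-negative and sum to one by construction.

This is a deliberately simplified analogue of per-gene mixed-model variance
partitioning: it reports the same kind of per-gene variance fractions but
does not fit a full REML mixed model (available optionally via
``method="reml"``, which uses statsmodels' variance components).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._errors import ConfoundingError, DesignError

__all__ = ["partition_variance"]


def _pair_design(samples: pd.DataFrame, factors: Sequence[str]):
    n = len(samples)
    pairs = list(combinations(range(n), 2))
    Z = np.ones((len(pairs), len(factors) + 1))
    for k, f in enumerate(factors):
        vals = samples[f].to_numpy()
        Z[:, k] = [vals[i] != vals[j] for i, j in pairs]
    return pairs, Z


def partition_variance(
    logcpm: pd.DataFrame,
    samples: pd.DataFrame,
    factors: Sequence[str] = ("line", "status", "batch"),
    method: str = "mom",
) -> pd.DataFrame:
    """Variance fractions per gene for each design factor plus residual.

    ``logcpm`` is genes x samples; ``samples`` a sample sheet whose
    ``sample_id`` order covers the columns.  Returns a DataFrame with one
    row per gene: ``gene_id``, one fraction column per factor, and
    ``residual``; fractions are in [0, 1] and sum to 1.
    """
    samples = (samples.set_index("sample_id").loc[list(logcpm.columns)]
               .rename_axis("sample_id").reset_index())
    for f in factors:
        if f not in samples.columns:
            raise DesignError(f"sample sheet lacks factor column {f!r}")
        if samples[f].nunique() < 2:
            raise DesignError(f"factor {f!r} has fewer than two levels")
    # aliased factors induce identical disagreement patterns and cannot be split
    pairs, Z = _pair_design(samples, factors)
    for (i, fa), (j, fb) in combinations(enumerate(factors), 2):
        if np.array_equal(Z[:, i], Z[:, j]):
            raise ConfoundingError(f"factors {fa!r} and {fb!r} are aliased")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ConfoundingError("factor disagreement patterns are collinear")

    if method == "reml":
        return _partition_reml(logcpm, samples, factors)
    if method != "mom":
        raise DesignError(f"unknown method {method!r}")

    y = logcpm.to_numpy(dtype=float)
    i_idx = np.array([i for i, _ in pairs])
    j_idx = np.array([j for _, j in pairs])
    half_sq = 0.5 * (y[:, i_idx] - y[:, j_idx]) ** 2

    comp = np.empty((y.shape[0], len(factors) + 1))
    for g in range(y.shape[0]):
        comp[g], _ = nnls(Z, half_sq[g])
    total = comp.sum(axis=1)
    frac = np.divide(comp, total[:, None], out=np.zeros_like(comp), where=total[:, None] > 0)
    # a constant gene has no variance to attribute: call it all residual
    frac[total == 0, -1] = 1.0

    out = pd.DataFrame(frac, columns=[*factors, "residual"])
    out.insert(0, "gene_id", logcpm.index.to_numpy())
    return out


def _partition_reml(logcpm, samples, factors):
    """REML variance components per gene via a mixed model (slow; optional)."""
    import statsmodels.api as sm

    data = samples.copy()
    vc = {f: f"0 + C({f})" for f in factors}
    groups = np.ones(len(samples))
    rows = []
    for g in logcpm.index:
        data["y"] = logcpm.loc[g].to_numpy()
        try:
            model = sm.MixedLM.from_formula(
                "y ~ 1", groups=groups, vc_formula=vc, re_formula="0", data=data
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
            comps = np.array([fit.vcomp[i] for i in range(len(factors))])
            resid = fit.scale
        except Exception:
            comps = np.zeros(len(factors))
            resid = float(np.var(data["y"], ddof=1))
        total = comps.sum() + resid
        frac = np.append(comps, resid) / total if total > 0 else np.append(np.zeros(len(factors)), 1.0)
        rows.append([g, *frac])
    return pd.DataFrame(rows, columns=["gene_id", *factors, "residual"])
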