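"""Negative-binomial dispersion estimation by adjusted profile likelihood.

The Cox-Reid adjusted profile log-likelihood (APL) of each gene is evaluated
on a fixed grid of dispersions; the common dispersion maximizes the mean APL
over genes and tagwise dispersions maximize a weighted-likelihood score that
adds ``prior_n`` pseudo-genes of the pooled curve to each gene's own, which
shrinks noisy per-gene estimates toward the common value.  Maxima are
refined by quadratic interpolation of the grid in log-dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._errors import DegenerateDataError, DesignError
from ..normalize import NormalizationFactors, effective_library_sizes
from ._irls import cr_adjustment, nb_irls
from .design import DesignMatrix

__all__ = ["DispersionEstimates", "estimate_dispersions"]

log = logging.getLogger(__name__)

#: default dispersion grid bounds (phi scale)
GRID_MIN, GRID_MAX, GRID_SIZE = 1e-6, 10.0, 36


@dataclass
class DispersionEstimates:
    """Common, optional trended, and tagwise NB dispersions (phi)."""

    common: float
    tagwise: pd.Series
    trended: pd.Series | None
    prior_df_equivalent: float

    def for_genes(self, gene_ids) -> np.ndarray:
        return self.tagwise.reindex(gene_ids).to_numpy()


def _interp_max(logphi: np.ndarray, score: np.ndarray) -> float:
    """Quadratic refinement of the grid argmax; returns log-phi."""
    i = int(np.argmax(score))
    if i == 0 or i == len(logphi) - 1:
        return float(logphi[i])
    x0, x1, x2 = logphi[i - 1], logphi[i], logphi[i + 1]
    y0, y1, y2 = score[i - 1], score[i], score[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= -1e-12:
        return float(x1)
    shift = 0.5 * (y0 - y2) / denom
    return float(np.clip(x1 + shift * (x2 - x1), x0, x2))


def _interp_max_rows(logphi: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Row-wise quadratic argmax refinement; ``scores`` is (G, K)."""
    G, K = scores.shape
    i = np.argmax(scores, axis=1)
    i_in = np.clip(i, 1, K - 2)
    y0 = scores[np.arange(G), i_in - 1]
    y1 = scores[np.arange(G), i_in]
    y2 = scores[np.arange(G), i_in + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(denom < -1e-12, 0.5 * (y0 - y2) / np.where(denom < -1e-12, denom, -1.0), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = logphi[1] - logphi[0]
    out = logphi[i_in] + shift * step
    boundary = (i == 0) | (i == K - 1)
    out[boundary] = logphi[i[boundary]]
    return out


def estimate_dispersions(
    counts: pd.DataFrame,
    design: DesignMatrix,
    factors: NormalizationFactors | pd.Series | None = None,
    prior_n: float = 10.0,
    trend: bool = False,
    grid: np.ndarray | None = None,
) -> DispersionEstimates:
    """Estimate common and tagwise NB dispersions for a count matrix.

    ``prior_n`` is the weight (in pseudo-genes) of the pooled likelihood in
    each gene's tagwise score; larger values shrink harder toward the common
    (or trended) value.  With ``trend=True`` a locally weighted fit of
    unshrunk log-dispersions on average log-CPM supplies a per-gene trended
    value, reported alongside.
    """
    X = design.X
    n, p = X.shape
    if counts.shape[1] != n:
        raise DesignError("counts and design have different numbers of samples")
    if n - p < 1:
        raise DegenerateDataError(
            "no residual degrees of freedom; supply a common dispersion "
            "from an external source instead of estimating one"
        )
    if grid is None:
        grid = np.exp(np.linspace(np.log(GRID_MIN), np.log(GRID_MAX), GRID_SIZE))
    logphi = np.log(grid)

    y = counts.to_numpy(dtype=float)
    expressed = y.sum(axis=1) > 0
    if not expressed.any():
        raise DegenerateDataError("all genes have zero counts")
    ye = y[expressed]
    G = ye.shape[0]
    offset = np.log(effective_library_sizes(counts, factors).to_numpy())

    apl = np.empty((G, len(grid)))
    beta_warm = None
    for k, phi_k in enumerate(grid):
        phi_vec = np.full(G, phi_k)
        beta, mu, ll, _ = nb_irls(ye, X, offset, phi_vec, beta0=beta_warm)
        beta_warm = beta
        apl[:, k] = ll - cr_adjustment(X, mu, phi_vec)

    pooled = apl.mean(axis=0)
    common = float(np.exp(_interp_max(logphi, pooled)))

    score = apl + prior_n * pooled[None, :]
    tag_log = _interp_max_rows(logphi, score)
    tagwise = np.exp(tag_log)

    trended_series = None
    if trend:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        unshrunk = np.exp(_interp_max_rows(logphi, apl))
        abund = np.log2(ye.mean(axis=1) + 0.5)
        fit = lowess(np.log(unshrunk), abund, frac=0.4, return_sorted=True)
        tr = np.interp(abund, fit[:, 0], fit[:, 1])
        trended_full = np.full(y.shape[0], common)
        trended_full[expressed] = np.exp(tr)
        trended_series = pd.Series(trended_full, index=counts.index, name="trended")
        # shrink toward the gene's trended value instead of the common one
        w = prior_n / (prior_n + 1.0)
        tagwise = np.exp((1 - w) * np.log(unshrunk + 1e-12) + w * tr)

    tag_full = np.full(y.shape[0], common)
    tag_full[expressed] = np.clip(tagwise, GRID_MIN, GRID_MAX)
    n_zero = int((~expressed).sum())
    if n_zero:
        log.info("%d all-zero genes assigned the common dispersion", n_zero)
    return DispersionEstimates(
        common=common,
        tagwise=pd.Series(tag_full, index=counts.index, name="tagwise"),
        trended=trended_series,
        prior_df_equivalent=float(prior_n),
    )
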