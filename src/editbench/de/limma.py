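"""Precision-weighted moderated t-statistics on log-CPM.

``precision_weights`` models the mean-variance relationship of log-CPM from
count data: per-gene linear models give residual standard deviations whose
square roots are smoothed against average log-count with a locally weighted
regression; each observation's predicted variance (at its own fitted
log-count) becomes an inverse-variance weight.

``weighted_moderated_t`` then fits weighted least squares per gene --
generalized least squares with a compound-symmetric within-block correlation
when a block factor and consensus correlation are supplied -- and shrinks the
residual variances toward a pooled prior by empirical Bayes before forming
t-statistics with augmented degrees of freedom.

``consensus_block_correlation`` estimates the single correlation shared by
replicates of the same block (e.g. sublines of one stock line): per-gene
moment estimates of the within-block residual correlation are
variance-stabilized with atanh, pooled by a trimmed mean, and transformed
back.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from scipy.stats import trim_mean

from .._errors import DegenerateDataError, DesignError, ParameterError
from ..normalize import NormalizationFactors, effective_library_sizes
from .design import DesignMatrix
from .result import make_de_result

__all__ = [
    "precision_weights",
    "consensus_block_correlation",
    "weighted_moderated_t",
    "fit_f_dist",
]

log = logging.getLogger(__name__)


def precision_weights(
    counts: pd.DataFrame,
    design: DesignMatrix,
    span: float = 0.5,
    factors: NormalizationFactors | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-CPM matrix and per-observation inverse-variance weights.

    Returns ``(logcpm, weights)`` as DataFrames of identical shape.  ``span``
    is the locally weighted regression span for the sqrt-sd vs mean
    log-count trend.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if not 0 < span <= 1:
        raise ParameterError("span must be in (0, 1]")
    X = design.X
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise DegenerateDataError("no residual degrees of freedom")
    if df_resid < 2:
        warnings.warn("fewer than 2 residual degrees of freedom; the variance trend is unstable")

    eff = effective_library_sizes(counts, factors).to_numpy()
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / (eff[None, :] + 1.0) * 1e6)

    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T  # G x p
    fitted = beta @ X.T
    resid = y - fitted
    s = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(s)

    # average log2 count of each gene, on the count (not CPM) scale
    mean_logcount = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    trend = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)

    # predicted sqrt-sd at each observation's own fitted log-count
    fitted_logcount = fitted + (np.log2(eff + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)
    w = pred**-4.0

    logcpm = pd.DataFrame(y, index=counts.index, columns=counts.columns)
    weights = pd.DataFrame(w, index=counts.index, columns=counts.columns)
    return logcpm, weights


def consensus_block_correlation(
    logcpm: pd.DataFrame,
    design: DesignMatrix,
    block,
    trim: float = 0.15,
) -> float:
    """Consensus within-block correlation of residuals across genes.

    Per gene, the mean bias-corrected cross-product of residuals over all
    within-block pairs, scaled by the residual variance, estimates the block
    correlation; estimates are atanh-transformed, pooled by a ``trim``-level
    trimmed mean, and transformed back.  The hat-matrix correction removes
    the spurious negative correlation that least-squares residuals of
    uncorrelated data exhibit.
    """
    block = pd.Series(np.asarray(block, dtype=object), index=logcpm.columns)
    pairs: list[tuple[int, int]] = []
    for _, idx in block.groupby(block).groups.items():
        pos = [logcpm.columns.get_loc(s) for s in idx]
        if len(pos) >= 2:
            pairs.extend(combinations(sorted(pos), 2))
    if not pairs:
        raise DesignError("no block has two or more members")

    X = design.X
    n, p = X.shape
    if n - p < 1:
        raise DegenerateDataError("no residual degrees of freedom")
    H = X @ np.linalg.pinv(X)
    y = logcpm.to_numpy(dtype=float)
    resid = y - y @ H.T
    s2 = (resid**2).sum(axis=1) / (n - p)

    i_idx = np.array([i for i, _ in pairs])
    j_idx = np.array([j for _, j in pairs])
    cross = resid[:, i_idx] * resid[:, j_idx] + s2[:, None] * H[i_idx, j_idx][None, :]
    ok = s2 > 1e-12
    if not ok.any():
        raise DegenerateDataError("all genes have zero residual variance")
    rho_g = cross[ok].mean(axis=1) / s2[ok]
    rho_g = np.clip(rho_g, -0.99, 0.99)
    rho = float(np.tanh(trim_mean(np.arctanh(rho_g), trim)))
    return float(np.clip(rho, -0.999, 0.999))


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Returns ``(prior_df, prior_var)``: the empirical-Bayes prior degrees of
    freedom and prior variance such that s2 ~ prior_var * F(df, prior_df).
    Uses the log-variance moments; an excess variance of zero or less gives
    an infinite prior df (all genes share one variance).
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess scatter beyond chi-square sampling noise: the degenerate
        # limit is one shared variance; the geometric mean leaves a set of
        # exactly equal variances unchanged
        return np.inf, float(np.exp(np.mean(z)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0


def _trigamma_inverse(y: float) -> float:
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _block_correlation_matrix(columns: pd.Index, block, rho: float) -> np.ndarray:
    R = np.eye(len(columns))
    block = pd.Series(np.asarray(block, dtype=object), index=columns)
    for _, idx in block.groupby(block).groups.items():
        pos = [columns.get_loc(s) for s in idx]
        for a in pos:
            for b in pos:
                if a != b:
                    R[a, b] = rho
    return R


def weighted_moderated_t(
    logcpm: pd.DataFrame,
    weights: pd.DataFrame,
    design: DesignMatrix,
    coef: int | None = None,
    block=None,
    rho: float | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test with precision weights.

    With ``block`` and ``rho`` given, each gene is fitted by generalized
    least squares under a compound-symmetric within-block correlation.
    ``prior_df`` overrides the estimated prior: 0 recovers the ordinary
    per-gene weighted t-test, ``inf`` tests every gene with the pooled
    variance.
    """
    if coef is None:
        coef = design.coef
    X = design.X
    n, p = X.shape
    if not 0 <= coef < p:
        raise DesignError("coefficient index out of range")
    df_resid = n - p
    if df_resid < 1:
        raise DegenerateDataError("no residual degrees of freedom")
    if (block is None) != (rho is None):
        raise DesignError("block and rho must be given together")

    y = logcpm.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    if (w <= 0).any():
        raise ParameterError("weights must be positive")
    G = y.shape[0]

    if block is not None:
        R = _block_correlation_matrix(logcpm.columns, block, float(rho))
    else:
        R = np.eye(n)
    d = 1.0 / np.sqrt(w)  # G x n per-observation sd scale
    sigma = R[None, :, :] * d[:, :, None] * d[:, None, :]  # G x n x n
    sigma_inv = np.linalg.inv(sigma)

    A = np.einsum("ni,gnm,mj->gij", X, sigma_inv, X, optimize=True)
    b = np.einsum("ni,gnm,gm->gi", X, sigma_inv, y, optimize=True)
    A_inv = np.linalg.inv(A)
    beta = np.einsum("gij,gj->gi", A_inv, b)
    ySy = np.einsum("gn,gnm,gm->g", y, sigma_inv, y, optimize=True)
    rss = np.maximum(ySy - np.einsum("gi,gi->g", b, beta), 0.0)
    s2 = rss / df_resid
    se_unscaled = np.sqrt(A_inv[:, coef, coef])

    if prior_df is None:
        d0, s0 = fit_f_dist(s2, df_resid)
    elif np.isinf(prior_df):
        d0, s0 = np.inf, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        s0 = fit_f_dist(s2, df_resid)[1] if d0 > 0 else 1.0

    if d0 == 0:
        s2_post = np.maximum(s2, 1e-10)
        df_total = float(df_resid)
    elif np.isinf(d0):
        s2_post = np.full(G, s0)
        df_total = 1e6
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = min(d0 + df_resid, 1e6)

    tstat = beta[:, coef] / (se_unscaled * np.sqrt(s2_post))
    pval = 2.0 * t_dist.sf(np.abs(tstat), df_total)

    method = "weighted_moderated_t_blocked" if block is not None else "weighted_moderated_t"
    contrast = design.columns[coef]
    return make_de_result(
        logcpm.index,
        beta[:, coef],
        pval,
        logcpm.mean(axis=1).to_numpy(),
        method=method,
        contrast=contrast,
    )
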