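"""Negative-binomial exact test for two-group comparisons.

Counts are first quantile-adjusted to a common effective library size
(mid-quantile NB-to-NB mapping), so that group sums are exchangeable under
the null.  Conditional on the total of each gene, the two-sided p-value sums
the probabilities of all group-sum splits that are no more likely than the
observed one (minimum-likelihood rule; tail-doubling available as an
option).  The group-sum distributions are NB because sums of i.i.d. NB
variables with shared dispersion are NB.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from .._errors import DesignError
from ..normalize import NormalizationFactors, cpm, effective_library_sizes
from .dispersion import DispersionEstimates
from .result import make_de_result

__all__ = ["nb_exact_test"]

_POISSON_PHI = 1e-8  # below this, treat the gene as Poisson


def _quantile_adjust(y: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Map counts to a common library size by matching NB mid-quantiles."""
    out = y.astype(float).copy()
    same = np.isclose(mu_in, mu_out, rtol=1e-9)
    todo = ~same
    if not todo.any():
        return out
    r = np.broadcast_to((1.0 / np.maximum(phi, _POISSON_PHI))[:, None], y.shape)
    pois = np.broadcast_to((phi <= _POISSON_PHI)[:, None], y.shape)
    p_in = r / (r + np.maximum(mu_in, 1e-12))
    p_out = r / (r + np.maximum(mu_out, 1e-12))

    sel = todo & ~pois
    q = nbinom.cdf(y[sel], r[sel], p_in[sel]) - 0.5 * nbinom.pmf(y[sel], r[sel], p_in[sel])
    q = np.clip(q, 1e-12, 1 - 1e-12)
    out[sel] = nbinom.ppf(q, r[sel], p_out[sel])

    sel = todo & pois
    if sel.any():
        q = poisson.cdf(y[sel], mu_in[sel]) - 0.5 * poisson.pmf(y[sel], mu_in[sel])
        q = np.clip(q, 1e-12, 1 - 1e-12)
        out[sel] = poisson.ppf(q, mu_out[sel])

    bad = ~np.isfinite(out)
    if bad.any():  # extreme quantiles: fall back to simple scaling
        scale = np.where(mu_in > 0, mu_out / np.maximum(mu_in, 1e-12), 1.0)
        out[bad] = y[bad] * scale[bad]
    return out


def _nb_logpmf(x: np.ndarray, size: float, prob: float) -> np.ndarray:
    # direct gammaln form avoids per-gene scipy dispatch overhead
    return (
        gammaln(x + size) - gammaln(size) - gammaln(x + 1.0)
        + size * np.log(prob) + x * np.log1p(-prob)
    )


def _binom_split_logpmf(t: int, frac1: float) -> np.ndarray:
    x = np.arange(t + 1)
    return (
        gammaln(t + 1.0) - gammaln(x + 1.0) - gammaln(t - x + 1.0)
        + x * np.log(frac1) + (t - x) * np.log1p(-frac1)
    )


def _two_sided_p(logp: np.ndarray, obs: int, method: str) -> float:
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    if method == "minlike":
        return float(min(1.0, probs[probs <= probs[obs] * (1.0 + 1e-8)].sum()))
    if method == "doubletail":
        lower = probs[: obs + 1].sum()
        upper = probs[obs:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown two-sided method {method!r}")


def nb_exact_test(
    counts: pd.DataFrame,
    group_labels,
    dispersions: DispersionEstimates,
    factors: NormalizationFactors | pd.Series | None = None,
    pair: tuple[str, str] | None = None,
    method: str = "minlike",
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Exact conditional NB test between two groups of samples.

    ``group_labels`` aligns with the columns of ``counts`` and must have
    exactly two levels.  ``pair = (reference, alternative)`` fixes the
    direction of the reported fold change (alternative over reference);
    by default ``stock`` is the reference when present, else the
    lexicographically first level.
    """
    labels = pd.Series(np.asarray(group_labels, dtype=object), index=counts.columns)
    levels = sorted(labels.unique().tolist())
    if len(levels) != 2:
        raise DesignError(f"exact test needs exactly two groups, got {len(levels)}")
    if pair is None:
        if "stock" in levels:
            ref = "stock"
            alt = [l for l in levels if l != "stock"][0]
        else:
            ref, alt = levels
    else:
        ref, alt = pair
        if set((ref, alt)) != set(levels):
            raise DesignError("pair does not match the group labels")
    in_ref = (labels == ref).to_numpy()
    in_alt = (labels == alt).to_numpy()
    n_ref, n_alt = int(in_ref.sum()), int(in_alt.sum())
    if n_ref == 0 or n_alt == 0:
        raise DesignError("both groups must be non-empty")

    y = counts.to_numpy(dtype=float)
    phi = np.maximum(dispersions.for_genes(counts.index), 0.0)
    eff = effective_library_sizes(counts, factors).to_numpy()
    # common library size: geometric mean of the two groups' geometric means
    n_common = float(np.sqrt(np.exp(np.mean(np.log(eff[in_ref]))) * np.exp(np.mean(np.log(eff[in_alt])))))
    rel = y.sum(axis=1) / eff.sum()

    mu_in = rel[:, None] * eff[None, :]
    mu_out = np.broadcast_to(rel[:, None] * n_common, y.shape)
    pseudo = _quantile_adjust(y, mu_in, mu_out, phi)

    s_ref = np.rint(pseudo[:, in_ref].sum(axis=1)).astype(np.int64)
    s_alt = np.rint(pseudo[:, in_alt].sum(axis=1)).astype(np.int64)
    mu0 = rel * n_common

    p = np.ones(y.shape[0])
    totals = s_ref + s_alt
    pois = phi <= _POISSON_PHI
    for g in np.flatnonzero(pois & (totals > 0)):
        logp = _binom_split_logpmf(int(totals[g]), n_alt / (n_alt + n_ref))
        p[g] = _two_sided_p(logp, int(s_alt[g]), method)
    nb_idx = np.flatnonzero(~pois & (totals > 0))
    # enumerate splits for blocks of genes with similar totals at once
    nb_idx = nb_idx[np.argsort(totals[nb_idx], kind="stable")]
    r_sum = 1.0 / phi
    p0_all = (1.0 / phi) / (1.0 / phi + mu0)
    for start in range(0, nb_idx.size, 256):
        idx = nb_idx[start : start + 256]
        t = totals[idx]
        tmax = int(t.max())
        x = np.arange(tmax + 1)
        valid = x[None, :] <= t[:, None]
        xa = np.minimum(x[None, :], t[:, None])
        xb = t[:, None] - xa
        ra = (n_alt * r_sum[idx])[:, None]
        rb = (n_ref * r_sum[idx])[:, None]
        p0 = p0_all[idx][:, None]
        lp = (
            gammaln(xa + ra) - gammaln(ra) - gammaln(xa + 1.0)
            + gammaln(xb + rb) - gammaln(rb) - gammaln(xb + 1.0)
            + (ra + rb) * np.log(p0) + t[:, None] * np.log1p(-p0)
        )
        lp[~valid] = -np.inf
        probs = np.exp(lp - lp.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        rows = np.arange(idx.size)
        obs_p = probs[rows, s_alt[idx]]
        if method == "minlike":
            pv = np.where(probs <= obs_p[:, None] * (1.0 + 1e-8), probs, 0.0).sum(axis=1)
        elif method == "doubletail":
            cum = np.cumsum(probs, axis=1)
            lower = cum[rows, s_alt[idx]]
            upper = 1.0 - cum[rows, s_alt[idx]] + obs_p
            pv = 2.0 * np.minimum(lower, upper)
        else:
            raise ValueError(f"unknown two-sided method {method!r}")
        p[idx] = np.minimum(pv, 1.0)

    m_ref = s_ref / n_ref
    m_alt = s_alt / n_alt
    log2fc = np.log2((m_alt + prior_count) / (m_ref + prior_count))
    mean_abund = cpm(counts, factors, log=True, prior_count=2.0).mean(axis=1).to_numpy()
    return make_de_result(
        counts.index, log2fc, p, mean_abund, method="exact", contrast=f"{alt} vs {ref}"
    )
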