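"""Library-size and composition normalization, CPM transforms, and sample PCA.

TMM (trimmed mean of M-values) corrects for library composition: each
sample's gene-wise log2 ratios against a reference sample (after library-size
scaling) are doubly trimmed -- by the log ratio M and by the average log
abundance A -- and averaged with inverse asymptotic-variance weights.  The
exponentiated mean is the sample's scaling factor; factors are rescaled to
geometric mean one so they only redistribute, never change, the total scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import DegenerateDataError, ParameterError

__all__ = [
    "NormalizationFactors",
    "tmm_factors",
    "effective_library_sizes",
    "cpm",
    "filter_low_expression",
    "PCAResult",
    "pca_samples",
]

log = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Per-sample composition scaling factors (geometric mean = 1)."""

    factors: pd.Series
    method: str
    trim_m: float
    trim_a: float
    reference_sample: str

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy()
    if (x < 0).any():
        raise ParameterError("counts must be non-negative")
    return np.asarray(x, dtype=float)


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    """Trimmed weighted mean of M-values for one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() < 10:
        raise DegenerateDataError(
            "fewer than 10 genes expressed in both sample and reference"
        )
    obs = obs[keep]
    ref = ref[keep]
    p_o = obs / n_obs
    p_r = ref / n_ref
    logr = np.log2(p_o / p_r)  # M
    abse = 0.5 * (np.log2(p_o) + np.log2(p_r))  # A
    if np.max(np.abs(logr)) < 1e-6:
        return 1.0
    # inverse asymptotic variance of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = logr.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(logr)
    rank_a = rankdata(abse)
    sel = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not sel.any():
        raise DegenerateDataError("trimming removed every gene")
    f = np.sum(logr[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        f = np.nansum(logr[sel]) / sel.sum()
    if abs(f) < 1e-10:
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormalizationFactors:
    """Compute TMM normalization factors for every sample.

    ``trim_m`` and ``trim_a`` are the fractions trimmed from *each* tail of
    the M and A distributions.  The reference sample, unless given, is the
    one whose upper-quartile of library-size-scaled counts is closest to the
    mean upper-quartile.
    """
    if counts.shape[1] < 2:
        raise DegenerateDataError("TMM needs at least two samples")
    x = _check_counts(counts)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise DegenerateDataError(f"samples with zero library size: {bad}")
    if reference is None:
        f75 = np.quantile(x / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference not in counts.columns:
            raise LookupError(f"unknown reference sample {reference!r}")
        ref_idx = counts.columns.get_loc(reference)

    factors = np.empty(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref_idx:
            factors[k] = 1.0
        else:
            factors[k] = _tmm_pair(x[:, k], x[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        method="TMM",
        trim_m=trim_m,
        trim_a=trim_a,
        reference_sample=str(counts.columns[ref_idx]),
    )


def effective_library_sizes(
    counts: pd.DataFrame, factors: NormalizationFactors | pd.Series | None = None
) -> pd.Series:
    """Library size times normalization factor, per sample."""
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        return lib
    f = factors.factors if isinstance(factors, NormalizationFactors) else factors
    f = f.reindex(counts.columns)
    if f.isna().any():
        raise LookupError("normalization factors do not cover all samples")
    return lib * f


def cpm(
    counts: pd.DataFrame,
    factors: NormalizationFactors | pd.Series | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million on effective (factor-adjusted) library sizes.

    With ``log=True`` the prior count is added on the count scale, scaled per
    sample in proportion to its effective library size, so that a zero count
    maps to a finite value and the transform is monotone in the raw count.
    """
    if prior_count < 0:
        raise ParameterError("prior_count must be >= 0")
    _check_counts(counts)
    eff = effective_library_sizes(counts, factors)
    if (eff <= 0).any():
        raise DegenerateDataError("zero effective library size")
    if not log:
        return counts / eff.to_numpy()[None, :] * 1e6
    prior = prior_count * eff.to_numpy() / eff.to_numpy().mean()
    adj_lib = eff.to_numpy() + 2.0 * prior
    vals = np.log2((counts.to_numpy() + prior[None, :]) / adj_lib[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def filter_low_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_cpm: float = 0.5,
    min_samples: int | None = None,
) -> pd.Series:
    """Boolean mask of genes with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    When ``min_samples`` is not given it defaults to the smallest
    (line, status) group size if a sample sheet is provided, else 1.  The
    default threshold is deliberately permissive; the applied filter is
    logged so it is visible in provenance.
    """
    if min_samples is None:
        if design is not None and {"line", "status"}.issubset(design.columns):
            min_samples = int(design.groupby(["line", "status"]).size().min())
        else:
            min_samples = 1
    if min_samples > counts.shape[1]:
        raise ParameterError("min_samples exceeds the number of samples")
    vals = cpm(counts, factors=None, log=False)
    mask = (vals >= min_cpm).sum(axis=1) >= min_samples
    log.info(
        "expression filter: CPM >= %g in >= %d samples keeps %d/%d genes",
        min_cpm, min_samples, int(mask.sum()), len(mask),
    )
    return mask


@dataclass
class PCAResult:
    """Sample-space principal components of a log-CPM matrix."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


def pca_samples(
    logcpm: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of samples on gene expression, with per-gene centering and scaling.

    Matches the usual ``prcomp(t(logcpm), center=TRUE, scale.=TRUE)``
    convention: genes are variables, samples are observations.  Genes with
    zero variance are dropped (with a logged warning) when ``scale`` is on,
    since scaling them is undefined.
    """
    if logcpm.shape[1] < 2:
        raise DegenerateDataError("PCA needs at least two samples")
    X = logcpm.to_numpy(dtype=float).T  # samples x genes
    genes = logcpm.index
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            log.warning("dropping %d zero-variance genes before scaled PCA", int((~keep).sum()))
            X = X[:, keep]
            sd = sd[keep]
            genes = genes[keep]
        if X.shape[1] == 0:
            raise DegenerateDataError("no genes with nonzero variance")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    k_full = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = k_full if n_components is None else min(n_components, k_full)
    comps = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=logcpm.columns, columns=comps)
    loadings = pd.DataFrame(vt[:k].T, index=genes, columns=comps)
    var_exp = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=var_exp)
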