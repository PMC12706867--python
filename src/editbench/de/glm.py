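"""Negative-binomial GLM with likelihood-ratio tests.

Per gene, a log-link NB GLM with fixed (estimated) dispersion is fitted by
IRLS under the full and the reduced design (the coefficient of interest
removed); twice the log-likelihood difference is referred to chi-square with
one degree of freedom.  Genes whose fit does not converge are reported with
``p = NaN`` and excluded from the BH correction rather than given a
fabricated significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .._errors import DesignError
from ..normalize import NormalizationFactors, cpm, effective_library_sizes
from ._irls import nb_irls
from .design import DesignMatrix
from .dispersion import DispersionEstimates
from .result import make_de_result

__all__ = ["nb_glm_lrt"]

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


def nb_glm_lrt(
    counts: pd.DataFrame,
    design: DesignMatrix,
    dispersions: DispersionEstimates,
    coef: int | None = None,
    factors: NormalizationFactors | pd.Series | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Likelihood-ratio test for one design coefficient, per gene.

    ``coef`` defaults to the design's coefficient of interest.  The reported
    ``log2fc`` is the coefficient of a prior-augmented fit converted to base
    2: a small library-size-scaled ``prior_count`` keeps fold changes of
    genes with zero counts in one condition finite and stable, while the
    likelihood-ratio statistic itself uses the unaugmented fits.
    """
    if coef is None:
        coef = design.coef
    X = design.X
    if not 0 <= coef < X.shape[1]:
        raise DesignError(f"coefficient index {coef} out of range for design")
    X_red = np.delete(X, coef, axis=1)
    if X_red.shape[1] == 0:
        raise DesignError("reduced design would be empty")
    if counts.shape[1] != X.shape[0]:
        raise DesignError("counts and design have different numbers of samples")

    y = counts.to_numpy(dtype=float)
    phi = dispersions.for_genes(counts.index)
    offset = np.log(effective_library_sizes(counts, factors).to_numpy())

    beta_f, _, ll_full, conv_f = nb_irls(y, X, offset, phi)
    _, _, ll_red, conv_r = nb_irls(y, X_red, offset, phi)

    stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    p = chi2.sf(stat, df=1)
    ok = conv_f & conv_r
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%d genes failed to converge; reported with p = NaN", n_bad)
        p[~ok] = np.nan

    if prior_count > 0:
        eff = np.exp(offset)
        y_aug = y + prior_count * (eff / eff.mean())[None, :]
        beta_rep, _, _, _ = nb_irls(y_aug, X, offset, phi, beta0=beta_f)
    else:
        beta_rep = beta_f
    log2fc = beta_rep[:, coef] / LN2
    mean_abund = cpm(counts, factors, log=True, prior_count=2.0).mean(axis=1).to_numpy()
    contrast = design.columns[coef]
    return make_de_result(
        counts.index, log2fc, p, mean_abund, method="glm_lrt", contrast=contrast
    )
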