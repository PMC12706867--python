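"""Benjamini-Hochberg step-up false discovery rate control."""

from __future__ import annotations

import numpy as np

from .._errors import ParameterError

__all__ = ["bh_adjust"]


def bh_adjust(p) -> np.ndarray:
    """Step-up BH adjusted p-values: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.

    NaN entries (e.g. non-converged model fits) are excluded from the number
    of tests ``m`` and propagate as NaN, so they can neither gain nor grant
    significance.  Values outside [0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    pf = p[finite]
    if ((pf < 0) | (pf > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[finite] = q
    return out
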