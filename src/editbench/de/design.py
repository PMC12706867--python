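"""Design matrices with treatment coding and a designated coefficient of interest."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .._errors import DesignError

__all__ = ["DesignMatrix", "design_matrix", "two_group_design"]


@dataclass
class DesignMatrix:
    """Coded design: rows are samples, columns are coded factors.

    ``coef`` indexes the coefficient of interest (the tested effect).
    """

    matrix: pd.DataFrame
    coef: int

    def __post_init__(self) -> None:
        X = self.matrix.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("design matrix is not full column rank")
        if not 0 <= self.coef < X.shape[1]:
            raise DesignError(f"coefficient index {self.coef} out of range")

    @property
    def X(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]

    def drop_coef(self) -> pd.DataFrame:
        """Reduced design without the coefficient of interest."""
        return self.matrix.drop(columns=self.matrix.columns[self.coef])


def _levels(values: pd.Series, reference_first: str | None = None) -> list:
    lv = sorted(pd.unique(values).tolist())
    if reference_first is not None and reference_first in lv:
        lv.remove(reference_first)
        lv.insert(0, reference_first)
    return lv


def design_matrix(
    samples: pd.DataFrame,
    factors: Sequence[str] = ("line", "status"),
    coef: str = "status",
) -> DesignMatrix:
    """Intercept plus treatment-coded factor columns from a sample sheet.

    ``coef`` names the factor whose (single) non-reference level is the
    effect of interest; it must have exactly two levels.  For ``status`` the
    reference level is ``stock`` so the coefficient is the editing effect.
    """
    if coef not in factors:
        raise DesignError(f"coef factor {coef!r} not among factors {list(factors)}")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    coef_col = None
    for f in factors:
        if f not in samples.columns:
            raise DesignError(f"sample sheet lacks factor column {f!r}")
        ref = "stock" if f == "status" else None
        lv = _levels(samples[f], reference_first=ref)
        if len(lv) < 2:
            raise DesignError(f"factor {f!r} has fewer than two levels")
        if f == coef and len(lv) != 2:
            raise DesignError(f"coefficient factor {f!r} must have exactly two levels")
        for level in lv[1:]:
            name = f"{f}[{level}]"
            cols[name] = (samples[f] == level).to_numpy(dtype=float)
            if f == coef:
                coef_col = name
    mat = pd.DataFrame(cols, index=pd.Index(samples["sample_id"], name="sample_id"))
    return DesignMatrix(matrix=mat, coef=mat.columns.get_loc(coef_col))


def two_group_design(sample_ids: Sequence[str], group1: Sequence[str]) -> DesignMatrix:
    """Intercept + indicator design for a two-group comparison.

    The coefficient of interest is membership in ``group1`` (log fold change
    of group1 over the rest).
    """
    ids = pd.Index(sample_ids)
    g1 = set(group1)
    missing = g1 - set(ids)
    if missing:
        raise DesignError(f"group1 samples not in sample_ids: {sorted(missing)[:5]}")
    ind = np.array([1.0 if s in g1 else 0.0 for s in ids])
    if ind.sum() == 0 or ind.sum() == len(ids):
        raise DesignError("both groups must be non-empty")
    mat = pd.DataFrame(
        {"intercept": np.ones(len(ids)), "group1": ind},
        index=pd.Index(ids, name="sample_id"),
    )
    return DesignMatrix(matrix=mat, coef=1)
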