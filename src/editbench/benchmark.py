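"""Spike-in performance benchmarking and reference-based evaluation.

The benchmark shuffles a line's samples through every possible null split,
injects known fold changes into one side of each split, reruns the DE
engine, and tallies detection: true/false positives per fold-change level,
sensitivity, specificity, and a rank-based AUC.  Because the splits are
null permutations, any unspiked gene that is called is a false positive by
construction.

``evaluate_against_reference`` scores a single line's significant set
against an aggregate multi-line reference list (the "common standard"
semantics): true positives are calls inside the reference, false positives
calls outside it, reported as percentages of the reference size and of the
line's total calls respectively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import DegenerateDataError, DesignError, ParameterError
from .de.result import significant_genes
from .pipelines import edit_contrast_de, two_group_de
from .simulate import DEFAULT_SPIKE_LEVELS, make_spikein_assignments, spike_fold_changes

__all__ = [
    "enumerate_null_splits",
    "roc_auc",
    "PerformanceTable",
    "run_spikein_benchmark",
    "ReferenceEvaluation",
    "evaluate_against_reference",
    "build_aggregate_reference",
]

log = logging.getLogger(__name__)


def enumerate_null_splits(
    sample_ids: Sequence[str], group_size: int, ordered: bool = False
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All distinct two-group partitions with the stated first-group size.

    Unordered by default: when the two groups have equal size, mirrored
    partitions count once (label-symmetric two-sided tests make them
    equivalent), so six samples in two groups of three give 10 splits.
    ``ordered=True`` keeps both orientations for asymmetric scoring.
    """
    ids = list(sample_ids)
    n = len(ids)
    if not 0 < group_size < n:
        raise ParameterError("group_size must be in (0, n)")
    splits = []
    first = ids[0]
    for combo in combinations(ids, group_size):
        g1 = tuple(combo)
        g2 = tuple(s for s in ids if s not in set(combo))
        if not ordered and 2 * group_size == n and first not in g1:
            continue  # mirror of a split already listed
        splits.append((g1, g2))
    return splits


def roc_auc(scores, truth) -> float:
    """Probability a perturbed gene outranks an unperturbed one (ties count 1/2).

    ``scores`` is a per-gene Series of continuous evidence (e.g. -log10 p);
    ``truth`` is a spike-in truth table (its ``gene_id`` column) or any
    iterable of perturbed gene ids.  Equals the trapezoidal area under the
    empirical ROC curve.
    """
    scores = pd.Series(scores).astype(float)
    if isinstance(truth, pd.DataFrame):
        truth_ids = set(truth["gene_id"])
    else:
        truth_ids = set(truth)
    labels = scores.index.isin(truth_ids)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("need at least one perturbed and one unperturbed gene")
    x = scores.to_numpy()
    if not np.isfinite(x).all():
        raise ParameterError("scores must be finite")
    if np.all(x == x[0]):
        warnings.warn("all scores tied; AUC is 0.5 by convention")
        return 0.5
    ranks = rankdata(x)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class PerformanceTable:
    """Aggregated spike-in detection performance per fold-change level."""

    table: pd.DataFrame  # level, tp, fn, fp, tn, sensitivity, specificity, auc
    fp_by_split: pd.DataFrame  # levels x splits false-positive counts
    engine: str
    q_threshold: float
    n_splits: int
    n_skipped: int = 0
    split_auc: pd.DataFrame | None = field(default=None, repr=False)


def run_spikein_benchmark(
    counts: pd.DataFrame,
    splits: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
    n_spike_genes: int = 50,
    levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
    engine: str = "exact",
    q_threshold: float = 0.05,
    seed: int = 0,
    mode: str = "per_level",
) -> PerformanceTable:
    """Spike known fold changes into null splits and score their detection.

    ``mode="per_level"`` runs one analysis per (split, level) with
    ``n_spike_genes`` spiked genes, so false-positive counts are comparable
    across levels; ``mode="combined"`` spikes all levels at once into a
    single analysis per split (the 50-genes-per-level reading that yields
    400 simultaneous perturbations with the default levels).
    """
    if mode not in ("per_level", "combined"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    levels = [float(lv) for lv in levels]
    tallies = {lv: dict(tp=0, fn=0, fp=0, tn=0) for lv in levels}
    fp_by_split = np.zeros((len(levels), len(splits)), dtype=int)
    auc_by_split = np.full((len(levels), len(splits)), np.nan)
    n_skipped = 0

    for si, (g1, g2) in enumerate(splits):
        sub = counts[list(g1) + list(g2)]
        level_groups: list[tuple[list[float], pd.DataFrame, pd.DataFrame]] = []
        if mode == "per_level":
            for lv in levels:
                genes, lvls = make_spikein_assignments(sub, n_spike_genes, [lv], rng)
                spiked, truth = spike_fold_changes(sub, genes, lvls, list(g1))
                level_groups.append(([lv], spiked, truth))
        else:
            genes, lvls = make_spikein_assignments(sub, n_spike_genes, levels, rng)
            spiked, truth = spike_fold_changes(sub, genes, lvls, list(g1))
            level_groups.append((levels, spiked, truth))

        for lvs, spiked, truth in level_groups:
            try:
                res = two_group_de(spiked, list(g1), engine=engine)
            except Exception as exc:  # engine failure: skip split, keep count
                log.warning("engine %s failed on split %d: %s", engine, si, exc)
                n_skipped += 1
                continue
            called = significant_genes(res, q_threshold)
            scores = pd.Series(
                -np.log10(np.maximum(res["p"].to_numpy(), 1e-300)),
                index=res["gene_id"],
            ).fillna(0.0)
            all_spiked = set(truth["gene_id"])
            unspiked = [g for g in res["gene_id"] if g not in all_spiked]
            fp = len(called & set(unspiked))
            tn = len(unspiked) - fp
            for lv in lvs:
                lv_genes = set(truth.loc[truth["level"] == lv, "gene_id"])
                tp = len(called & lv_genes)
                tallies[lv]["tp"] += tp
                tallies[lv]["fn"] += len(lv_genes) - tp
                tallies[lv]["fp"] += fp
                tallies[lv]["tn"] += tn
                li = levels.index(lv)
                fp_by_split[li, si] = fp
                sel = scores.loc[list(lv_genes) + unspiked]
                auc_by_split[li, si] = roc_auc(sel, lv_genes)

    rows = []
    for li, lv in enumerate(levels):
        t = tallies[lv]
        denom_p = t["tp"] + t["fn"]
        denom_n = t["tn"] + t["fp"]
        rows.append(
            {
                "level": lv,
                "tp": t["tp"],
                "fn": t["fn"],
                "fp": t["fp"],
                "tn": t["tn"],
                "sensitivity": t["tp"] / denom_p if denom_p else np.nan,
                "specificity": t["tn"] / denom_n if denom_n else np.nan,
                "auc": float(np.nanmean(auc_by_split[li])) if np.isfinite(auc_by_split[li]).any() else np.nan,
            }
        )
    return PerformanceTable(
        table=pd.DataFrame(rows),
        fp_by_split=pd.DataFrame(fp_by_split, index=pd.Index(levels, name="level")),
        engine=engine,
        q_threshold=q_threshold,
        n_splits=len(splits),
        n_skipped=n_skipped,
        split_auc=pd.DataFrame(auc_by_split, index=pd.Index(levels, name="level")),
    )


def _round1_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ReferenceEvaluation:
    """One line's significant calls scored against an aggregate reference."""

    line: str
    engine: str
    total_significant: int
    tp: int
    fp: int
    tp_pct: float  # 100 * tp / reference_size, half-up to one decimal
    fp_pct: float  # 100 * fp / total_significant, half-up to one decimal
    reference_size: int
    no_calls: bool = False


def evaluate_against_reference(
    line_result: pd.DataFrame,
    reference: set[str],
    q_threshold: float = 0.05,
    line: str = "",
) -> ReferenceEvaluation:
    """Score a per-line DE result against an aggregate reference gene list.

    True positives are significant genes inside the reference, false
    positives those outside; ``tp + fp`` equals the line's total significant
    count exactly.
    """
    reference = set(reference)
    if not reference:
        raise DegenerateDataError("empty reference set")
    universe = set(line_result["gene_id"])
    if not reference <= universe:
        raise DesignError("reference contains genes absent from the result's universe")
    sig = significant_genes(line_result, q_threshold)
    tp = len(sig & reference)
    fp = len(sig - reference)
    total = len(sig)
    method = line_result["method"].iloc[0] if len(line_result) else ""
    if total == 0:
        return ReferenceEvaluation(
            line=line, engine=method, total_significant=0, tp=0, fp=0,
            tp_pct=0.0, fp_pct=0.0, reference_size=len(reference), no_calls=True,
        )
    return ReferenceEvaluation(
        line=line,
        engine=method,
        total_significant=total,
        tp=tp,
        fp=fp,
        tp_pct=_round1_half_up(100.0 * tp / len(reference)),
        fp_pct=_round1_half_up(100.0 * fp / total),
        reference_size=len(reference),
    )


def build_aggregate_reference(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    engine: str = "glm",
    q_threshold: float = 0.05,
) -> set[str]:
    """Significant genes of the joint line-adjusted edited-vs-stock analysis.

    All lines are normalized together and analysed with a model that
    accounts for baseline line differences (GLM with line covariates, or the
    blocked moderated t).  The exact test has no way to adjust for line and
    is rejected.
    """
    if engine == "exact":
        raise DesignError("the exact test cannot adjust for line; use glm or wmt")
    lines = samples.loc[samples["sample_id"].isin(counts.columns), "line"].unique()
    if len(lines) < 2:
        raise DesignError("aggregate reference requires at least two lines")
    res = edit_contrast_de(counts, samples, engine=engine, adjust_line=True)
    return significant_genes(res, q_threshold)
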