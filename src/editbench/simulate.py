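"""Synthetic RNA-seq count generation for gene-edited iPSC designs.

The generator emulates the structure of a multi-stock-line gene-editing
experiment: several independent stock iPSC lines, each contributing a set of
independently cultured control replicates and a set of gene-edited sublines.
Counts follow a negative-binomial model on a log2-additive mean scale,

    mu[g, s] = libsize[s] * baseline[g]
               * 2 ** (line_offset + batch_offset + status * edit_effect
                       [+ heterogeneity shift])

with per-gene dispersion phi_g so that Var = mu + phi * mu^2.  Every injected
effect is recorded in a truth table so downstream detection performance can be
scored against known ground truth.

The default parameters describe the study conditions the package targets:
26 485 annotated genes, four stock lines with three stock replicates and
three edited sublines each, library sizes around 60 million reads, a strong
negative log2 fold change on an HPRT1-like gene (a premature stop codon
subject to nonsense-mediated decay), sparse secondary edit effects, and a
sparse batch effect confined to the first culture batch ("A").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import DesignError, ParameterError

__all__ = [
    "Heterogeneity",
    "SimulationParams",
    "make_design",
    "simulate_counts",
    "spike_fold_changes",
    "make_spikein_assignments",
    "DEFAULT_SPIKE_LEVELS",
]

#: fold-change levels used by the spike-in benchmark: 1.5x, 2x, 3x, 5x and
#: their inverses.
DEFAULT_SPIKE_LEVELS: tuple[float, ...] = (1.5, 2.0, 3.0, 5.0, 1 / 1.5, 0.5, 1 / 3, 0.2)

HPRT1_GENE = "HPRT1"


@dataclass(frozen=True)
class Heterogeneity:
    """Subclone-selection artifact affecting one line's edited sublines.

    Models a heterogeneous stock line in which isolating an edited subclone
    captures a subpopulation whose expression differs from the parent culture
    for reasons unrelated to the edit.

    Parameters
    ----------
    line
        Line identifier the artifact applies to.
    n_genes
        Number of randomly chosen genes shifted in the affected sublines.
    log2_shift
        Standard deviation of the per-gene log2 shifts (drawn once per
        affected subline, i.e. sublines differ from each other too).
    subline_fraction
        Fraction of that line's edited sublines affected (rounded up, >= 1).
    """

    line: str
    n_genes: int = 500
    log2_shift: float = 1.0
    subline_fraction: float = 1.0


@dataclass
class SimulationParams:
    """Parameters of the negative-binomial count generator.

    Defaults reproduce the study conditions (see module docstring).  The
    baseline is drawn on the natural-log scale and normalized to relative
    abundances summing to one, so ``libsize`` retains its usual meaning.
    Dispersions are gamma-distributed; shape 2.0 with scale 0.03 puts the
    median near 0.05, typical for technical iPSC replicates.
    """

    n_genes: int = 26_485
    baseline_logmean: tuple[float, float] = (0.0, 1.8)
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.03
    dispersion_trend: float = 0.0  # >0 inflates dispersion of low-abundance genes
    libsize_logmean: float = math.log(60e6)
    libsize_logsd: float = 0.08
    sigma_line: float = 0.5
    sigma_batch: float = 0.5
    batch_gene_fraction: float = 0.10
    batch_label: str = "A"
    edit_effects: Mapping[str, float] | None = None
    n_edit_genes: int = 100
    edit_effect_range: tuple[float, float] = (0.5, 2.0)
    hprt1_log2fc: float = -3.0
    heterogeneity: Heterogeneity | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.dispersion_shape <= 0 or self.dispersion_scale <= 0:
            raise ParameterError("dispersion gamma parameters must be > 0")
        for name in ("sigma_line", "sigma_batch", "libsize_logsd", "dispersion_trend"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.batch_gene_fraction <= 1:
            raise ParameterError("batch_gene_fraction must be in [0, 1]")
        if self.edit_effects is not None and len(self.edit_effects) > self.n_genes:
            raise ParameterError("more edit effects than genes")
        if self.edit_effects is None and self.n_edit_genes + 1 > self.n_genes:
            raise ParameterError("n_edit_genes + 1 exceeds n_genes")


def make_design(
    n_lines: int = 4,
    n_stock: int = 3,
    n_edited: int = 3,
    batches: Sequence[str] = ("A", "B", "C"),
) -> pd.DataFrame:
    """Build the sample sheet for an ``n_lines x (n_stock + n_edited)`` design.

    Stock replicates of each line cycle through the culture batches; edited
    sublines are independent clones and also carry a batch label from their
    culture round.  The default reproduces the 4-line study layout with
    12 stock and 12 edited samples.

    Returns a DataFrame with columns ``sample_id, line, status, subline,
    batch``; ``status`` is ``stock`` or ``edited``.
    """
    if n_lines < 1 or n_stock < 1 or n_edited < 1:
        raise DesignError("n_lines, n_stock and n_edited must all be >= 1")
    if not batches:
        raise DesignError("at least one batch label is required")
    rows = []
    for i in range(n_lines):
        line = f"L{i + 1}"
        for j in range(n_stock):
            batch = batches[j % len(batches)]
            rows.append(
                dict(
                    sample_id=f"{line}_stock_{j + 1}",
                    line=line,
                    status="stock",
                    subline=line,
                    batch=batch,
                )
            )
        for j in range(n_edited):
            batch = batches[j % len(batches)]
            rows.append(
                dict(
                    sample_id=f"{line}_edit_{j + 1}",
                    line=line,
                    status="edited",
                    subline=f"{line}.e{j + 1}",
                    batch=batch,
                )
            )
    sheet = pd.DataFrame(rows)
    if sheet["sample_id"].duplicated().any():
        raise DesignError("duplicate sample ids in design")
    return sheet


def _default_edit_effects(params: SimulationParams, gene_ids: np.ndarray, rng: np.random.Generator) -> dict[str, float]:
    """HPRT1-like knockdown plus sparse secondary effects of mixed sign."""
    effects: dict[str, float] = {HPRT1_GENE: params.hprt1_log2fc}
    candidates = [g for g in gene_ids if g != HPRT1_GENE]
    chosen = rng.choice(len(candidates), size=params.n_edit_genes, replace=False)
    lo, hi = params.edit_effect_range
    mags = rng.uniform(lo, hi, size=params.n_edit_genes)
    signs = rng.choice([-1.0, 1.0], size=params.n_edit_genes)
    for idx, m, s in zip(chosen, mags, signs):
        effects[candidates[idx]] = float(m * s)
    return effects


def simulate_counts(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a negative-binomial count matrix for the given sample sheet.

    Returns ``(counts, truth)``: an integer genes x samples DataFrame and a
    truth table with columns ``gene_id, true_log2fc, affected`` recording the
    injected edit effects (the edited-vs-stock contrast).  Line, batch and
    heterogeneity offsets are nuisance structure and are deliberately not part
    of the truth table.

    The draw is fully determined by ``params.seed``: the same parameters give
    a bit-identical matrix.
    """
    if len(design) == 0:
        raise DesignError("empty design")
    required = {"sample_id", "line", "status", "batch"}
    if not required.issubset(design.columns):
        raise DesignError(f"design must have columns {sorted(required)}")
    params.validate()

    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    n_samples = len(design)

    gene_ids = np.array([f"G{i + 1:06d}" for i in range(n_genes)], dtype=object)
    gene_ids[0] = HPRT1_GENE

    mu_b, sd_b = params.baseline_logmean
    raw = rng.lognormal(mean=mu_b, sigma=sd_b, size=n_genes)
    baseline = raw / raw.sum()  # relative abundances

    phi = rng.gamma(params.dispersion_shape, params.dispersion_scale, size=n_genes)
    phi = np.maximum(phi, 1e-8)
    if params.dispersion_trend > 0:
        # low-abundance genes get inflated dispersion, a mild decreasing trend
        q = pd.Series(baseline).rank(pct=True).to_numpy()
        phi = phi * (1.0 + params.dispersion_trend * (1.0 - q))

    libsize = rng.lognormal(params.libsize_logmean, params.libsize_logsd, size=n_samples)

    log2_offset = np.zeros((n_genes, n_samples))

    # per-line per-gene baseline offsets
    for line in pd.unique(design["line"]):
        cols = (design["line"] == line).to_numpy()
        if params.sigma_line > 0:
            log2_offset[:, cols] += rng.normal(0.0, params.sigma_line, size=n_genes)[:, None]
        else:
            rng.normal(size=n_genes)  # keep stream position stable across sigma settings

    # sparse batch effect on the designated batch
    batch_genes = rng.random(n_genes) < params.batch_gene_fraction
    batch_shift = rng.normal(0.0, params.sigma_batch, size=n_genes) * batch_genes
    in_batch = (design["batch"] == params.batch_label).to_numpy()
    if params.sigma_batch > 0:
        log2_offset[:, in_batch] += batch_shift[:, None]

    # edit effects on edited samples
    effects = dict(params.edit_effects) if params.edit_effects is not None else _default_edit_effects(params, gene_ids, rng)
    gene_index = pd.Index(gene_ids)
    unknown = [g for g in effects if g not in gene_index]
    if unknown:
        raise ParameterError(f"edit_effects reference unknown genes: {unknown[:5]}")
    edited = (design["status"] == "edited").to_numpy()
    effect_vec = np.zeros(n_genes)
    for g, lfc in effects.items():
        effect_vec[gene_index.get_loc(g)] = lfc
    log2_offset[:, edited] += effect_vec[:, None]

    # optional heterogeneous-line artifact on a subset of edited sublines
    het = params.heterogeneity
    if het is not None:
        line_edit = edited & (design["line"] == het.line).to_numpy()
        subs = np.flatnonzero(line_edit)
        if subs.size == 0:
            raise ParameterError(f"heterogeneity line {het.line!r} has no edited samples")
        n_aff = max(1, math.ceil(het.subline_fraction * subs.size))
        affected_samples = rng.choice(subs, size=min(n_aff, subs.size), replace=False)
        het_genes = rng.choice(n_genes, size=min(het.n_genes, n_genes), replace=False)
        for s in affected_samples:
            shifts = rng.normal(0.0, het.log2_shift, size=het_genes.size)
            log2_offset[het_genes, s] += shifts

    mu = libsize[None, :] * baseline[:, None] * np.exp2(log2_offset)
    if not np.all(np.isfinite(mu)) or mu.max() > 1e12:
        raise ParameterError("expected counts overflow; reduce offsets or library size")

    # gamma-Poisson mixture == negative binomial with Var = mu + phi mu^2
    shape = (1.0 / phi)[:, None]
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=pd.Index(design["sample_id"], name="sample_id"))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_log2fc": effect_vec,
            "affected": effect_vec != 0.0,
        }
    )
    for g in effects:  # zero-magnitude assignments still count as targeted
        truth.loc[truth["gene_id"] == g, "affected"] = True
    return counts_df, truth


def spike_fold_changes(
    counts: pd.DataFrame,
    genes: Sequence[str],
    levels: Sequence[float] | float,
    target_samples: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply selected genes' counts by known fold changes in target samples.

    ``levels`` is either one level applied to every gene in ``genes`` or a
    sequence aligned with ``genes`` (one level per gene).  Counts are
    multiplied and rounded to the nearest integer; all other entries are
    returned untouched (the output is a copy).

    Returns ``(spiked_counts, truth)`` where the truth table has one row per
    (gene, level) perturbation with columns ``gene_id, level, log2fc, target``.
    """
    if np.isscalar(levels):
        levels = [float(levels)] * len(genes)
    levels = [float(x) for x in levels]
    if len(levels) != len(genes):
        raise ParameterError("levels must be scalar or aligned with genes")
    if any(lv <= 0 for lv in levels):
        raise ParameterError("fold-change levels must be > 0")
    missing = [g for g in genes if g not in counts.index]
    if missing:
        raise LookupError(f"unknown gene ids: {missing[:5]}")
    missing_s = [s for s in target_samples if s not in counts.columns]
    if missing_s:
        raise LookupError(f"unknown sample ids: {missing_s[:5]}")
    if len(set(genes)) != len(genes):
        raise ParameterError("spiked genes must be unique")

    out = counts.copy()
    cols = list(target_samples)
    for g, lv in zip(genes, levels):
        out.loc[g, cols] = np.rint(counts.loc[g, cols].to_numpy() * lv).astype(np.int64)
    truth = pd.DataFrame(
        {
            "gene_id": list(genes),
            "level": levels,
            "log2fc": np.log2(levels),
            "target": ",".join(cols),
        }
    )
    return out, truth


def make_spikein_assignments(
    counts: pd.DataFrame,
    n_genes_per_level: int = 50,
    levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[str], list[float]]:
    """Pick distinct random genes for each fold-change level.

    With the default 50 genes per level and the eight canonical levels this
    yields 400 perturbations.  Genes with zero counts in every sample are
    excluded from the draw: a fold change on an all-zero gene is undetectable
    by construction and would deflate sensitivity artifactually.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eligible = counts.index[(counts.to_numpy() > 0).any(axis=1)]
    need = n_genes_per_level * len(levels)
    if len(eligible) < need:
        raise ParameterError(
            f"need {need} genes with nonzero counts, only {len(eligible)} available"
        )
    chosen = rng.choice(len(eligible), size=need, replace=False)
    genes = [eligible[i] for i in chosen]
    lvls = [float(lv) for lv in levels for _ in range(n_genes_per_level)]
    return genes, lvls


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
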