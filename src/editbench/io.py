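"""Reading and writing the package's tabular conventions.

Counts travel as TSV (first column gene id, header row of sample ids) or as
MatrixMarket with ``genes.tsv``/``samples.tsv`` sidecars; sample sheets,
truth tables, DE results and normalization factors as TSV; simulation
parameters as YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from ._errors import ParameterError
from .simulate import Heterogeneity, SimulationParams

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_de_result",
    "write_de_result",
    "write_factors",
    "read_params_yaml",
    "write_params_yaml",
]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
        raise ParameterError(f"{path}: counts must be non-negative numbers")
    if not np.allclose(vals, np.rint(vals)):
        raise ParameterError(f"{path}: counts must be integers")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_counts_mtx(counts: pd.DataFrame, directory) -> None:
    """MatrixMarket triple: matrix.mtx + genes.tsv + samples.tsv sidecars."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(d / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(d / "samples.tsv", sep="\t", index=False, header=False)


def read_counts_mtx(directory) -> pd.DataFrame:
    d = Path(directory)
    mat = spio.mmread(d / "matrix.mtx").toarray().astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0]
    samples = pd.read_csv(d / "samples.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=list(samples))


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "line", "status"}
    if not required.issubset(df.columns):
        raise ParameterError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_de_result(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_de_result(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index=False)


def write_factors(factors, path) -> None:
    f = factors.factors if hasattr(factors, "factors") else factors
    f.rename("factor").to_csv(path, sep="\t", index_label="sample_id")


def write_params_yaml(params: SimulationParams, path) -> None:
    d = dataclasses.asdict(params)
    if d.get("heterogeneity") is not None:
        d["heterogeneity"] = dataclasses.asdict(params.heterogeneity)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_params_yaml(path) -> SimulationParams:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if d.get("heterogeneity") is not None:
        d["heterogeneity"] = Heterogeneity(**d["heterogeneity"])
    for k in ("baseline_logmean", "edit_effect_range"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = set(d) - known
    if unknown:
        raise ParameterError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimulationParams(**d)
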