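"""Reading and writing count datasets as a 10x-style Matrix Market triple.

Layout of a dataset directory::

    matrix.mtx      genes x cells sparse integer counts (MatrixMarket)
    barcodes.tsv    one cell id per line (matrix columns)
    features.tsv    gene_id plus category flag columns (matrix rows)
    cells.tsv       per-cell metadata (sample_id, age, sex, genotype, cell_type)

``matrix.mtx`` follows the CellRanger convention of genes as rows and
cells as columns; in memory the orientation is cells x genes (AnnData).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .synthetic import GENE_CATEGORIES

__all__ = ["write_counts", "read_counts", "ParseError"]


class ParseError(ValueError):
    """A dataset directory is malformed or internally inconsistent."""


def write_counts(adata: AnnData, path: str | Path) -> Path:
    """Write ``adata`` (raw counts) to ``path`` as an MTX + TSV directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if adata.n_obs == 0:
        warnings.warn("writing an empty matrix (0 cells)")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(path / "matrix.mtx", X.T.astype(np.int64))
    pd.Series(adata.obs_names, name="cell_id").to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False)
    features = adata.var.copy()
    features.insert(0, "gene_id", adata.var_names)
    features.to_csv(path / "features.tsv", sep="\t", index=False)
    cells = adata.obs.copy()
    cells.insert(0, "cell_id", adata.obs_names)
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    return path


def read_counts(path: str | Path) -> AnnData:
    """Read a dataset directory written by :func:`write_counts`.

    Raises :class:`ParseError` when the matrix and its sidecar tables
    disagree in dimensions, naming the offending file.
    """
    path = Path(path)
    try:
        X = scipy.io.mmread(path / "matrix.mtx")
    except Exception as e:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path / 'matrix.mtx'}: malformed MatrixMarket file ({e})") from e
    X = sp.csr_matrix(X.T).astype(np.int32)

    try:
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)
    if len(barcodes) != X.shape[0]:
        raise ParseError(
            f"{path / 'barcodes.tsv'}: {len(barcodes)} barcodes but matrix has "
            f"{X.shape[0]} cells")
    features = pd.read_csv(path / "features.tsv", sep="\t")
    if "gene_id" not in features.columns:
        raise ParseError(f"{path / 'features.tsv'}: missing 'gene_id' column")
    if len(features) != X.shape[1]:
        raise ParseError(
            f"{path / 'features.tsv'}: {len(features)} features but matrix has "
            f"{X.shape[1]} genes")
    var = features.set_index("gene_id")
    for cat in var.columns.intersection(GENE_CATEGORIES):
        var[cat] = var[cat].astype(bool)

    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    if "cell_id" not in cells.columns:
        raise ParseError(f"{path / 'cells.tsv'}: missing 'cell_id' column")
    if len(cells) != X.shape[0]:
        raise ParseError(
            f"{path / 'cells.tsv'}: {len(cells)} rows but matrix has "
            f"{X.shape[0]} cells")
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    if not obs.index.equals(pd.Index(barcodes.values, name=obs.index.name)):
        raise ParseError(f"{path / 'cells.tsv'}: cell_id order differs from barcodes.tsv")

    if X.shape[0] == 0:
        warnings.warn(f"{path}: dataset has 0 cells")
    adata = AnnData(X=X, obs=obs, var=var)
    if "age" in adata.obs.columns:
        ages = [a for a in adata.obs["age"].drop_duplicates()]
        adata.obs["age"] = pd.Categorical(adata.obs["age"], categories=_age_order(ages),
                                          ordered=True)
        adata.uns["ages"] = list(adata.obs["age"].cat.categories)
    for col in ("sample_id", "sex", "genotype", "cell_type"):
        if col in adata.obs.columns:
            adata.obs[col] = adata.obs[col].astype("category")
    return adata


def _age_order(ages: list[str]) -> list[str]:
    """Order stage labels embryonic-first (E before P), then numerically."""
    def key(a: str):
        prefix = 0 if a.startswith("E") else 1
        try:
            num = float(a[1:])
        except ValueError:
            num = np.inf
        # embryonic days count down toward birth
        return (prefix, num if prefix else num)
    return sorted(set(ages), key=key)
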