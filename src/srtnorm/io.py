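"""Readers and writers for the on-disk formats.

Count matrices travel either as Matrix Market triplets with ``genes.tsv`` /
``cells.tsv`` sidecars or as a dense CSV (cells x genes, header = gene ids,
first column = cell ids). Cell tables are plain CSV.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import CountMatrix, validate_cell_table


def write_mtx(counts: CountMatrix, directory: str | os.PathLike) -> Path:
    """Write a matrix as ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(counts.values))
    (directory / "genes.tsv").write_text("\n".join(counts.gene_ids) + "\n")
    (directory / "cells.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    return directory


def read_mtx(directory: str | os.PathLike) -> CountMatrix:
    directory = Path(directory)
    raw = spio.mmread(directory / "matrix.mtx")
    values = np.asarray(raw.todense()) if sparse.issparse(raw) else np.asarray(raw)
    genes = (directory / "genes.tsv").read_text().split()
    cells = (directory / "cells.tsv").read_text().split()
    return CountMatrix(values, genes, cells)


def write_counts_csv(counts: CountMatrix, path: str | os.PathLike) -> Path:
    """Dense CSV dialect: rows = cells, columns = genes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(counts.values.T, index=counts.cell_ids, columns=counts.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path)
    return path


def read_counts_csv(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.values.T, list(df.columns), [str(c) for c in df.index])


def read_counts(path: str | os.PathLike) -> CountMatrix:
    """Dispatch on layout: a directory means Matrix Market, a file means CSV."""
    path = Path(path)
    if path.is_dir():
        return read_mtx(path)
    return read_counts_csv(path)


def write_cell_table(cells: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_cell_table(cells)
    cells.to_csv(path, index=False)
    return path


def read_cell_table(path: str | os.PathLike) -> pd.DataFrame:
    cells = pd.read_csv(path, dtype={"cell_id": str, "subpop": str})
    return validate_cell_table(cells)
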