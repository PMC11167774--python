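"""Core data containers shared by every analysis stage.

The universal substrate is a genes x cells count matrix with identifier
sidecars, plus a per-cell metadata table (position, subpopulation label,
Z-center, volume/area).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: columns a complete cell table carries; ``area`` is optional.
CELL_TABLE_COLUMNS = ("cell_id", "x", "y", "subpop", "z_center", "volume", "area")


@dataclass
class CountMatrix:
    """Genes x cells nonnegative expression matrix with identifier sidecars.

    Values are integers at generation time but may become fractional after
    capture thinning or normalization-style scaling, so the container only
    enforces nonnegativity and shape consistency.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell identifiers must be unique")
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message detail
            raise KeyError(f"gene {exc.args[0]!r} not present in matrix") from exc

    def cell_index(self, cell_ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in cell_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"cell {exc.args[0]!r} not present in matrix") from exc

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(gene_ids)
        return CountMatrix(self.values[idx, :], list(gene_ids), list(self.cell_ids))

    def subset_cells(self, cell_ids: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index(cell_ids)
        return CountMatrix(self.values[:, idx], list(self.gene_ids), list(cell_ids))

    def cell_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), list(self.gene_ids), list(self.cell_ids))


@dataclass
class NormalizedMatrix:
    """Normalized expression with provenance of how it was produced."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    method: str = "none"
    panel: str = "full"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape does not match identifier sidecars")
        if np.any(self.values < 0):
            raise ValueError("normalized values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)


def validate_cell_table(cells: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a cell table against its contract (one row per cell, volumes > 0)."""
    if "cell_id" not in cells.columns:
        raise ValueError("cell table must have a cell_id column")
    if cells["cell_id"].duplicated().any():
        raise ValueError("cell table has duplicate cell_id rows")
    if "volume" in cells.columns:
        vol = cells["volume"].dropna()
        if (vol <= 0).any():
            raise ValueError("cell volumes must be strictly positive")
    if counts is not None:
        missing = set(counts.cell_ids) - set(cells["cell_id"])
        if missing:
            raise ValueError(f"{len(missing)} cells in matrix missing from cell table")
    return cells


def align_cells(counts: CountMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    """Return the cell table reindexed to the matrix column order."""
    validate_cell_table(cells, counts)
    return cells.set_index("cell_id").loc[counts.cell_ids].reset_index()
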