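"""Spatially variable gene detection on rasterized normalized expression.

Cells are aggregated into fixed-size square bins (mean per bin), bin values
are log10(x+1)-transformed, and each gene is tested for spatial
autocorrelation with Moran's I over row-standardized k-nearest-neighbor bin
weights, using a permutation null. Permutation seeds are derived stably per
gene so that cross-panel comparisons are not polluted by resampling noise.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from .core import NormalizedMatrix
from .de import bh_adjust


@dataclass
class RasterGrid:
    """Per-bin mean expression on a half-open square grid."""

    bin_size: float
    bin_x: np.ndarray          # integer bin indices
    bin_y: np.ndarray
    n_cells: np.ndarray        # occupancy per bin
    values: np.ndarray         # genes x bins
    gene_ids: list[str]

    @property
    def n_bins(self) -> int:
        return len(self.bin_x)

    def centers(self) -> np.ndarray:
        return np.column_stack([(self.bin_x + 0.5) * self.bin_size,
                                (self.bin_y + 0.5) * self.bin_size])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, gid in enumerate(self.gene_ids):
            rows.append(pd.DataFrame({
                "bin_x": self.bin_x, "bin_y": self.bin_y, "gene": gid,
                "value": self.values[g], "n_cells": self.n_cells,
            }))
        return pd.concat(rows, ignore_index=True)


def rasterize(norm: NormalizedMatrix, cells: pd.DataFrame, bin_size: float = 50.0) -> RasterGrid:
    """Average expression of the cells falling in each occupied bin.

    Bins are half-open squares [k*s, (k+1)*s); a cell exactly on an edge
    belongs to the higher bin.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    pos = cells.set_index("cell_id").loc[norm.cell_ids, ["x", "y"]].to_numpy(dtype=float)
    ix = np.floor(pos[:, 0] / bin_size).astype(int)
    iy = np.floor(pos[:, 1] / bin_size).astype(int)
    keys, inverse = np.unique(np.column_stack([ix, iy]), axis=0, return_inverse=True)
    n_bins = len(keys)
    occupancy = np.bincount(inverse, minlength=n_bins).astype(float)
    # genes x bins sums via one sparse matmul
    assign = sparse.csr_matrix(
        (np.ones(norm.n_cells), (np.arange(norm.n_cells), inverse)),
        shape=(norm.n_cells, n_bins))
    sums = norm.values @ assign
    values = np.asarray(sums) / occupancy[None, :]
    return RasterGrid(bin_size, keys[:, 0], keys[:, 1], occupancy.astype(int),
                      values, list(norm.gene_ids))


def log_transform(grid: RasterGrid) -> RasterGrid:
    """log10(value + 1) per bin."""
    if np.any(grid.values < 0):
        raise ValueError("raster values must be nonnegative")
    return RasterGrid(grid.bin_size, grid.bin_x, grid.bin_y, grid.n_cells,
                      np.log10(grid.values + 1.0), list(grid.gene_ids))


def knn_weights(grid: RasterGrid, k: int = 6) -> np.ndarray:
    """Row-standardized k-nearest-neighbor weight matrix over bin centers."""
    n = grid.n_bins
    if n < 3:
        raise ValueError("need at least 3 bins for spatial testing")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(grid.centers())
    _, idx = nn.kneighbors(grid.centers())
    w = np.zeros((n, n))
    for i in range(n):
        neighbors = idx[i, 1:]  # drop self
        w[i, neighbors] = 1.0 / len(neighbors)
    return w


def _is_constant(values: np.ndarray) -> bool:
    # relative tolerance: binning identical cell values can leave ~1e-16
    # roundoff jitter that must still count as a constant field
    return bool(np.ptp(values) <= 1e-10 * max(1.0, float(np.max(np.abs(values)))))


def morans_i(z: np.ndarray, w: np.ndarray) -> float:
    """Moran's I with row-standardized weights: (n/S0) z'Wz / z'z, S0 = n."""
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero-variance field")
    return float(z @ (w @ z) / denom)


def _gene_seed(seed: int, gene: str) -> int:
    """Stable per-gene permutation seed: identical across panels and methods."""
    return (int(seed) * 1_000_003 + zlib.crc32(gene.encode())) % (2 ** 32)


def morans_i_test(grid: RasterGrid, gene: str, w: np.ndarray | None = None,
                  n_perm: int = 999, seed: int = 0, k: int = 6) -> tuple[float, float]:
    """Permutation test for positive spatial autocorrelation of one gene.

    p = (1 + #{permuted I >= observed I}) / (1 + n_perm). Returns (I, p);
    raises on a zero-variance field.
    """
    if w is None:
        w = knn_weights(grid, k=k)
    values = grid.values[grid.gene_ids.index(gene)]
    if _is_constant(values):
        raise ValueError(f"gene {gene!r} has zero variance across bins")
    obs = morans_i(values, w)
    rng = np.random.default_rng(_gene_seed(seed, gene))
    z = values - values.mean()
    denom = float(z @ z)
    count = 0
    for _ in range(n_perm):
        zp = rng.permutation(z)
        if float(zp @ (w @ zp)) / denom >= obs - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return obs, p


def run_svg(norm: NormalizedMatrix, cells: pd.DataFrame, bin_size: float = 50.0,
            n_perm: int = 999, seed: int = 0, k: int = 6) -> pd.DataFrame:
    """Rasterize, log-transform and test every gene; BH-adjust across genes.

    Zero-variance genes are flagged (NaN statistic and p) and excluded from
    the adjustment family.
    """
    grid = log_transform(rasterize(norm, cells, bin_size=bin_size))
    w = knn_weights(grid, k=k)
    stat = np.full(len(grid.gene_ids), np.nan)
    p = np.full(len(grid.gene_ids), np.nan)
    for g, gene in enumerate(grid.gene_ids):
        if _is_constant(grid.values[g]):
            continue
        stat[g], p[g] = morans_i_test(grid, gene, w=w, n_perm=n_perm, seed=seed)
    p_adj = np.full_like(p, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        p_adj[defined] = bh_adjust(p[defined])
    return pd.DataFrame({"gene": grid.gene_ids, "moran_i": stat,
                         "p": p, "p_adj": p_adj})


def svg_error_rates(skewed: pd.DataFrame, full: pd.DataFrame,
                    alpha: float = 0.05, readjust: bool = True) -> dict:
    """SVG FNR (and FPR when true negatives exist) vs full-panel truth.

    With ``readjust`` (default) adjusted p-values are recomputed over the
    shared gene family so runs with identical raw p-values score identically
    despite different panel sizes.
    """
    shared = skewed.merge(full, on="gene", suffixes=("_skew", "_full"),
                          how="inner", validate="one_to_one")
    shared = shared.dropna(subset=["p_skew", "p_full"])
    if shared.empty:
        raise ValueError("no shared testable genes between the two runs")
    if readjust:
        shared = shared.copy()
        shared["p_adj_skew"] = bh_adjust(shared["p_skew"].to_numpy())
        shared["p_adj_full"] = bh_adjust(shared["p_full"].to_numpy())
    sig_s = shared["p_adj_skew"].to_numpy() < alpha
    sig_f = shared["p_adj_full"].to_numpy() < alpha
    fn = int(np.sum(~sig_s & sig_f))
    tp = int(np.sum(sig_s & sig_f))
    fp = int(np.sum(sig_s & ~sig_f))
    tn = int(np.sum(~sig_s & ~sig_f))
    fnr = None if fn + tp == 0 else fn / (fn + tp)
    fpr = None if fp + tn == 0 else fp / (fp + tn)
    return {"fnr": fnr, "fpr": fpr, "FN": fn, "TP": tp, "FP": fp, "TN": tn}


def svg_fnr(skewed: pd.DataFrame, full: pd.DataFrame, alpha: float = 0.05) -> float | None:
    return svg_error_rates(skewed, full, alpha=alpha)["fnr"]
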