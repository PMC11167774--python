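"""Per-cell scaling factors under five schemes plus Pearson-residual normalization.

All factor methods are implemented from their defining computations:

* ``library_size`` — sum of counts per cell.
* ``poscounts`` — median-of-ratios against modified geometric means that
  average log counts over all cells but only positive entries (robust to
  zeros).
* ``tmm`` — trimmed mean of M-values against a reference cell with
  precision weights; singleton pairing handles cells sharing no positive
  genes with the reference.
* ``volume`` / ``area`` — measured cell geometry, independent of counts.

Normalized expression is counts divided by the per-cell factor. Pearson
residual normalization is the analytic negative-binomial offset model with
fixed dispersion, clipped and floored at zero.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import CountMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)

METHODS = ("none", "library_size", "poscounts", "tmm", "volume", "area")


@dataclass
class ScalingFactors:
    """Per-cell positive divisors with method tag and rescaling convention."""

    cell_ids: list[str]
    factors: np.ndarray
    method: str
    rescale: str = "none"

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.cell_ids),):
            raise ValueError("one factor per cell required")
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise ValueError("scaling factors must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        unit = self.factors / self.factors.mean()
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "method": self.method,
            "factor": self.factors,
            "factor_unit_mean": unit,
        })


def filter_zero_cells(counts: CountMatrix) -> tuple[CountMatrix, dict]:
    """Drop cells whose panel total is zero; report a census of the filter."""
    totals = counts.cell_totals()
    keep = totals > 0
    census = {
        "n_cells_in": counts.n_cells,
        "n_cells_kept": int(keep.sum()),
        "n_cells_dropped": int((~keep).sum()),
    }
    if census["n_cells_dropped"]:
        logger.info("dropped %d/%d cells with zero panel counts",
                    census["n_cells_dropped"], census["n_cells_in"])
        kept_ids = [c for c, k in zip(counts.cell_ids, keep) if k]
        counts = counts.subset_cells(kept_ids)
    return counts, census


def library_size_factors(counts: CountMatrix) -> ScalingFactors:
    """Factor = total detected counts per cell."""
    totals = counts.cell_totals()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered first")
    return ScalingFactors(list(counts.cell_ids), totals, "library_size")


def poscounts_factors(counts: CountMatrix) -> ScalingFactors:
    """Median-of-ratios with positive-count modified geometric means.

    For gene g the reference is exp(mean over *all* cells of log counts,
    summing logs over positive entries only); a cell's factor is the median
    of count/reference over genes positive in that cell with a positive
    reference.
    """
    v = counts.values
    n_cells = counts.n_cells
    logs = np.zeros_like(v)
    np.log(v, out=logs, where=v > 0)
    geo = np.exp(logs.sum(axis=1) / n_cells)
    geo[~(v > 0).any(axis=1)] = 0.0
    eligible = geo > 0
    if not eligible.any():
        raise ValueError("no gene has a positive modified geometric mean")
    factors = np.empty(n_cells)
    for i in range(n_cells):
        mask = eligible & (v[:, i] > 0)
        if not mask.any():
            raise ValueError(
                f"cell {counts.cell_ids[i]!r} has no positive counts on eligible genes")
        factors[i] = np.median(v[mask, i] / geo[mask])
    _warn_if_degenerate(factors)
    return ScalingFactors(list(counts.cell_ids), factors, "poscounts")


def _warn_if_degenerate(factors: np.ndarray) -> None:
    # Sparse data can collapse median-of-ratios factors onto 0 or 1,
    # behaving like no normalization.
    near = (np.abs(factors) < 1e-6) | (np.abs(factors - 1.0) < 1e-6)
    if near.mean() > 0.5:
        warnings.warn(
            "more than half of the size factors are degenerate (near 0 or 1); "
            "the data may be too sparse for median-of-ratios normalization",
            RuntimeWarning, stacklevel=3)


def _tmm_reference(v: np.ndarray) -> int:
    """Cell whose 75th percentile of count proportions is closest to the mean."""
    totals = v.sum(axis=0)
    with np.errstate(invalid="ignore"):
        q75 = np.percentile(v / totals[None, :], 75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_one(ci: np.ndarray, cr: np.ndarray, ni: float, nr: float,
             trim_m: float, trim_a: float) -> float:
    """log2 normalization factor of one cell against the reference."""
    both = (ci > 0) & (cr > 0)
    if both.sum() >= 2:
        pi = ci[both] / ni
        pr = cr[both] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        w = (ni - ci[both]) / (ni * ci[both]) + (nr - cr[both]) / (nr * cr[both])
    else:
        # Singleton pairing: genes positive in exactly one of the pair,
        # ranked by magnitude and matched up.
        only_i = np.sort(ci[(ci > 0) & (cr == 0)])[::-1]
        only_r = np.sort(cr[(cr > 0) & (ci == 0)])[::-1]
        k = min(len(only_i), len(only_r))
        if k == 0:
            return 0.0
        pi = only_i[:k] / ni
        pr = only_r[:k] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        w = (ni - only_i[:k]) / (ni * only_i[:k]) + (nr - only_r[:k]) / (nr * only_r[:k])
    if np.allclose(m, m[0]):
        keep = np.ones(len(m), dtype=bool)
    else:
        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not keep.any():
        return 0.0
    w = np.where(w > 0, w, np.inf)
    inv = 1.0 / w[keep]
    if inv.sum() == 0:
        return float(np.mean(m[keep]))
    return float(np.sum(m[keep] * inv) / inv.sum())


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                reference: int | str | None = None,
                convention: str = "inverse") -> ScalingFactors:
    """Trimmed-mean-of-M-values factors against a reference cell.

    The raw edgeR-style normalization factor f has geometric mean 1 across
    cells. ``convention="inverse"`` (default) returns 1/f as the divisor (counts
    are multiplied by f); ``convention="effective"`` returns N_i * f_i, the
    normalized-library-size divisor.
    """
    if counts.n_cells < 2:
        raise ValueError("TMM needs at least two cells")
    v = counts.values
    totals = v.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered first")
    if reference is None:
        ref = _tmm_reference(v)
    elif isinstance(reference, str):
        ref = counts.cell_ids.index(reference)
    else:
        ref = int(reference)
    cr = v[:, ref]
    nr = totals[ref]
    log2f = np.array([
        0.0 if i == ref else _tmm_one(v[:, i], cr, totals[i], nr, trim_m, trim_a)
        for i in range(counts.n_cells)
    ])
    log2f -= log2f.mean()  # geometric mean of f equals 1
    f = 2.0 ** log2f
    if convention == "inverse":
        factors = 1.0 / f
    elif convention == "effective":
        factors = totals * f
    else:
        raise ValueError(f"unknown TMM convention {convention!r}")
    return ScalingFactors(list(counts.cell_ids), factors, "tmm")


def volume_factors(cells: pd.DataFrame, use: str = "volume",
                   cell_ids: list[str] | None = None) -> ScalingFactors:
    """Factor = measured cell volume (or area); independent of counts."""
    if use not in ("volume", "area"):
        raise ValueError("use must be 'volume' or 'area'")
    table = cells.set_index("cell_id")
    ids = list(cell_ids) if cell_ids is not None else [str(c) for c in cells["cell_id"]]
    vals = table.loc[ids, use].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError(f"every retained cell needs a positive {use}")
    return ScalingFactors(ids, vals, use)


def rescale_unit_mean(factors: ScalingFactors) -> ScalingFactors:
    """Divide factors by their arithmetic mean so cross-panel scales match."""
    if len(factors.cell_ids) == 0:
        raise ValueError("empty factor vector")
    return replace(factors, factors=factors.factors / factors.factors.mean(),
                   rescale="unit_mean")


def normalize(counts: CountMatrix, factors: ScalingFactors | None,
              panel: str = "full") -> NormalizedMatrix:
    """Divide each cell's counts by its scaling factor."""
    if factors is None:
        return NormalizedMatrix(counts.values.copy(), list(counts.gene_ids),
                                list(counts.cell_ids), method="none", panel=panel)
    if list(factors.cell_ids) != list(counts.cell_ids):
        if set(factors.cell_ids) != set(counts.cell_ids):
            raise ValueError("factors do not cover exactly the cells in the matrix")
        idx = counts.cell_index(factors.cell_ids)
        fac = np.empty(counts.n_cells)
        fac[idx] = factors.factors
    else:
        fac = factors.factors
    return NormalizedMatrix(counts.values / fac[None, :], list(counts.gene_ids),
                            list(counts.cell_ids), method=factors.method, panel=panel)


def compute_factors(counts: CountMatrix, method: str,
                    cells: pd.DataFrame | None = None) -> ScalingFactors | None:
    """Dispatch a factor method by name (``none`` returns ``None``)."""
    if method == "none":
        return None
    if method == "library_size":
        return library_size_factors(counts)
    if method == "poscounts":
        return poscounts_factors(counts)
    if method == "tmm":
        return tmm_factors(counts)
    if method in ("volume", "area"):
        if cells is None:
            raise ValueError(f"{method} factors need a cell table")
        return volume_factors(cells, use=method, cell_ids=list(counts.cell_ids))
    raise ValueError(f"unknown normalization method {method!r}")


def pearson_residual_normalize(counts: CountMatrix, theta: float = 100.0,
                               clip: float | None = None,
                               panel: str = "full") -> NormalizedMatrix:
    """Analytic negative-binomial Pearson residuals as normalized expression.

    mu_gi = (gene total * cell total) / grand total; residuals are clipped
    above at sqrt(n_cells) by default and negatives are set to zero.
    """
    v = counts.values
    grand = v.sum()
    if grand <= 0:
        raise ValueError("grand total of counts is zero")
    mu = np.outer(v.sum(axis=1), v.sum(axis=0)) / grand
    denom = np.sqrt(mu + mu * mu / theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = np.where(denom > 0, (v - mu) / np.where(denom > 0, denom, 1.0), 0.0)
    if clip is None:
        clip = np.sqrt(counts.n_cells)
    res = np.clip(res, 0.0, clip)
    return NormalizedMatrix(res, list(counts.gene_ids), list(counts.cell_ids),
                            method="pearson", panel=panel)
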