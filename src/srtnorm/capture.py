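"""Partial capture of spherical cells by a finite stack of imaging Z-planes.

A cell is modeled as a sphere centered at its Z-position. The imaging stack
captures an effective slab extending half a depth of field beyond the
outermost planes; the captured fraction of a cell is the fraction of its
sphere volume inside the slab, computed from spherical-cap geometry. Counts
are thinned by the captured fraction, either deterministically or by
binomial sampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix

#: group codes: 1 center above slab, 2 crossing top from inside, 3 fully
#: inside, 4 crossing bottom from inside, 5 center below slab.
GROUP_ABOVE, GROUP_TOP, GROUP_INSIDE, GROUP_BOTTOM, GROUP_BELOW = 1, 2, 3, 4, 5


@dataclass
class CaptureConfig:
    """Geometry of the imaging stack."""

    n_planes: int = 7
    plane_spacing: float = 1.5
    depth_of_field: float = 0.678
    bottom_plane_z: float = 0.0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("need at least one imaging plane")
        if self.plane_spacing <= 0:
            raise ValueError("plane_spacing must be positive")
        if self.depth_of_field < 0:
            raise ValueError("depth_of_field must be nonnegative")


def capture_bounds(config: CaptureConfig) -> tuple[float, float]:
    """Effective slab: half a depth of field beyond the outermost planes."""
    z_bot = config.bottom_plane_z - 0.5 * config.depth_of_field
    z_top = (config.bottom_plane_z
             + (config.n_planes - 1) * config.plane_spacing
             + 0.5 * config.depth_of_field)
    return z_bot, z_top


def cap_fraction(r: float, h: float) -> float:
    """Fraction of a sphere's volume in a cap of height ``h``: h^2(3r-h)/(4r^3)."""
    r = float(r)
    h = float(h)
    if r <= 0:
        raise ValueError("radius must be positive")
    if not 0.0 <= h <= 2.0 * r + 1e-12 * r:
        raise ValueError(f"cap height {h} outside [0, 2r] for r={r}")
    h = min(h, 2.0 * r)
    return h * h * (3.0 * r - h) / (4.0 * r ** 3)


def _cap_fraction_vec(r: np.ndarray, h: np.ndarray) -> np.ndarray:
    h = np.clip(h, 0.0, 2.0 * r)
    return h * h * (3.0 * r - h) / (4.0 * r ** 3)


def captured_fraction(z_c: np.ndarray | float, r: np.ndarray | float,
                      config: CaptureConfig) -> np.ndarray | float:
    """Fraction of sphere volume inside the slab; continuous in ``z_c``.

    Computed as the difference of two cap fractions measured from the bottom
    of the sphere, which covers every overlap geometry (including spheres
    crossing both boundaries at once) with one formula.
    """
    z_bot, z_top = capture_bounds(config)
    z_c = np.asarray(z_c, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    h_top = np.clip(z_top - z_c + r, 0.0, 2.0 * r)
    h_bot = np.clip(z_bot - z_c + r, 0.0, 2.0 * r)
    frac = _cap_fraction_vec(r, h_top) - _cap_fraction_vec(r, h_bot)
    frac = np.clip(frac, 0.0, 1.0)  # guard float roundoff at the boundaries
    # exact endpoints where the sphere is fully inside / fully outside,
    # so group 3 <=> P_v == 1 holds without float fuzz
    frac = np.where((z_c - r >= z_bot) & (z_c + r <= z_top), 1.0, frac)
    frac = np.where((z_c - r >= z_top) | (z_c + r <= z_bot), 0.0, frac)
    return frac if frac.ndim else float(frac)


def classify_group(z_c: np.ndarray | float, r: np.ndarray | float,
                   config: CaptureConfig) -> np.ndarray | int:
    """Five-way classification of a cell against the effective slab."""
    z_bot, z_top = capture_bounds(config)
    z_c = np.atleast_1d(np.asarray(z_c, dtype=float))
    r = np.broadcast_to(np.asarray(r, dtype=float), z_c.shape)
    group = np.full(z_c.shape, GROUP_INSIDE, dtype=int)
    above = z_c > z_top
    below = z_c < z_bot
    crosses_top = (~above) & (~below) & (z_c + r > z_top)
    crosses_bot = (~above) & (~below) & (~crosses_top) & (z_c - r < z_bot)
    group[above] = GROUP_ABOVE
    group[below] = GROUP_BELOW
    group[crosses_top] = GROUP_TOP
    group[crosses_bot] = GROUP_BOTTOM
    return group if group.size > 1 else int(group[0])


def classify_and_capture(z_c: float, r: float, config: CaptureConfig) -> tuple[int, float]:
    """Group code and captured volume fraction for a single cell."""
    if r <= 0:
        raise ValueError("radius must be positive")
    group = classify_group(z_c, r, config)
    frac = captured_fraction(z_c, r, config)
    return int(group), float(frac)


def capture_table(cells: pd.DataFrame, config: CaptureConfig) -> pd.DataFrame:
    """Per-cell capture result: cell_id, group, captured_fraction, captured_volume.

    Radii derive from the ``volume`` column via the sphere volume formula.
    """
    from .synthetic import sphere_radius

    z_c = cells["z_center"].to_numpy(dtype=float)
    vol = cells["volume"].to_numpy(dtype=float)
    r = np.asarray(sphere_radius(vol))
    frac = np.atleast_1d(captured_fraction(z_c, r, config))
    group = np.atleast_1d(classify_group(z_c, r, config))
    return pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "group": group,
        "captured_fraction": frac,
        "captured_volume": vol * frac,
    })


def apply_capture(counts: CountMatrix, fractions: np.ndarray,
                  mode: str = "scale", seed: int | None = None) -> CountMatrix:
    """Thin counts by per-cell captured fractions.

    ``scale`` multiplies each cell's profile by its fraction (fractional
    counts allowed); ``binomial`` draws seeded binomial thinning instead.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (counts.n_cells,):
        raise ValueError("need exactly one captured fraction per cell")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("captured fractions must lie in [0, 1]")
    if mode == "scale":
        values = counts.values * fractions[None, :]
    elif mode == "binomial":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        values = rng.binomial(counts.values.astype(int), fractions[None, :]).astype(float)
    else:
        raise ValueError(f"unknown capture mode {mode!r}")
    return CountMatrix(values, list(counts.gene_ids), list(counts.cell_ids))
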