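"""Seeded generators for im-SRT-like and scRNA-seq-like datasets.

The count model is gamma-Poisson: each gene draws a base mean from a gamma
distribution, each cell draws a multiplicative library factor from a
log-normal, and each subpopulation upweights a random fraction of genes by a
log-normal enrichment factor. Counts are Poisson around the product. Spatial
structure places each subpopulation in its own axis-aligned block so that
subpopulation-enriched genes are spatially variable; Z-centers and volumes
feed the partial-capture simulation.
"""
from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix


def _subpop_labels(n: int) -> list[str]:
    alphabet = string.ascii_uppercase
    if n <= len(alphabet):
        return list(alphabet[:n])
    return [f"S{i}" for i in range(n)]


@dataclass
class SimConfig:
    """Parameters of the gamma-Poisson generator."""

    n_genes: int = 500
    n_cells: int = 2000
    subpop_proportions: tuple[float, ...] = (0.5, 0.5)
    de_prob: float = 0.1
    de_fc_location: float = 1.0
    de_fc_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_location: float = math.log(150.0)
    lib_scale: float = 0.35
    dropout: bool = False
    dropout_midpoint: float = 0.0
    dropout_shape: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_cells < 2:
            raise ValueError("need at least 2 genes and 2 cells")
        props = np.asarray(self.subpop_proportions, dtype=float)
        if props.ndim != 1 or len(props) < 1 or np.any(props < 0):
            raise ValueError("subpop_proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subpop_proportions must sum to 1 within 1e-9")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        for name in ("de_fc_scale", "mean_shape", "mean_rate", "lib_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def subpops(self) -> list[str]:
        return _subpop_labels(len(self.subpop_proportions))


@dataclass
class SpatialLayout:
    """Axis-aligned rectangle (x0, x1, y0, y1) in um per subpopulation."""

    region_blocks: dict[str, tuple[float, float, float, float]]
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name, (x0, x1, y0, y1) in self.region_blocks.items():
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"degenerate block for subpopulation {name!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")

    @classmethod
    def side_by_side(cls, subpops, block_width: float = 200.0,
                     block_height: float = 400.0, jitter_sd: float = 0.0) -> "SpatialLayout":
        blocks = {
            s: (i * block_width, (i + 1) * block_width, 0.0, block_height)
            for i, s in enumerate(subpops)
        }
        return cls(blocks, jitter_sd)


@dataclass
class ZVolumeConfig:
    """Z-center and volume distributions used by the capture simulation."""

    z_mean_by_subpop: dict[str, float] = field(
        default_factory=lambda: {"A": 4.839, "B": 12.0})
    z_sd: float = 1.5
    volume_mean: float = 1000.0
    volume_sd: float = 2000.0

    def __post_init__(self) -> None:
        if self.z_sd <= 0:
            raise ValueError("z_sd must be positive")
        if self.volume_mean <= 0:
            raise ValueError("volume_mean must be positive")
        if self.volume_sd < 0:
            raise ValueError("volume_sd must be nonnegative")


@dataclass
class SimResult:
    """Counts plus cell metadata and the simulation's DE ground truth."""

    counts: CountMatrix
    cells: pd.DataFrame
    de_genes: dict[str, dict[str, float]]  # subpop -> {gene_id: drawn factor}


def _largest_remainder_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer subpopulation sizes matching the proportions, summing to n."""
    raw = proportions * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def simulate_counts(config: SimConfig,
                    lib_multiplier: np.ndarray | None = None) -> SimResult:
    """Draw a gamma-Poisson count matrix with subpopulation-enriched genes.

    Returns integer counts, a partial cell table (cell_id, subpop) and the
    per-subpopulation DE ground truth (gene -> drawn enrichment factor).
    ``lib_multiplier`` scales each cell's library factor (used to couple
    expression to cell volume).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng_gene = np.random.default_rng(seeds[0])
    rng_cell = np.random.default_rng(seeds[1])
    rng_de = np.random.default_rng(seeds[2])
    rng_noise = np.random.default_rng(seeds[3])

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    cell_ids = [f"c{i:05d}" for i in range(config.n_cells)]
    subpops = config.subpops

    base_mean = rng_gene.gamma(config.mean_shape, 1.0 / config.mean_rate,
                               size=config.n_genes)
    # Base means act as expression proportions; the library factor sets the
    # expected per-cell total (before subpopulation enrichment), so
    # exp(lib_location) is the typical library size.
    base_prop = base_mean / base_mean.sum()
    lib = rng_cell.lognormal(config.lib_location, config.lib_scale,
                             size=config.n_cells)
    if lib_multiplier is not None:
        lib_multiplier = np.asarray(lib_multiplier, dtype=float)
        if lib_multiplier.shape != (config.n_cells,) or np.any(lib_multiplier <= 0):
            raise ValueError("lib_multiplier must be positive, one value per cell")
        lib = lib * lib_multiplier
    sizes = _largest_remainder_counts(np.asarray(config.subpop_proportions, float),
                                      config.n_cells)
    labels = np.repeat(subpops, sizes)

    n_de = int(round(config.de_prob * config.n_genes))
    de_factor = np.ones((config.n_genes, len(subpops)))
    de_genes: dict[str, dict[str, float]] = {}
    for j, s in enumerate(subpops):
        chosen = rng_de.choice(config.n_genes, size=n_de, replace=False)
        factors = rng_de.lognormal(config.de_fc_location, config.de_fc_scale,
                                   size=n_de)
        de_factor[chosen, j] = factors
        de_genes[s] = {gene_ids[g]: float(f) for g, f in zip(chosen, factors)}

    subpop_idx = np.repeat(np.arange(len(subpops)), sizes)
    mu = base_prop[:, None] * lib[None, :] * de_factor[:, subpop_idx]
    values = rng_noise.poisson(mu).astype(float)
    if config.dropout:
        logit = np.clip(config.dropout_shape * (np.log(mu + 1e-12) - config.dropout_midpoint),
                        -700, 700)
        p_drop = 1.0 / (1.0 + np.exp(-logit))
        values *= rng_noise.random(mu.shape) >= p_drop

    counts = CountMatrix(values, gene_ids, cell_ids)
    cells = pd.DataFrame({"cell_id": cell_ids, "subpop": labels})
    return SimResult(counts, cells, de_genes)


def assign_positions(cells: pd.DataFrame, layout: SpatialLayout, seed: int = 0) -> pd.DataFrame:
    """Place each cell uniformly in its subpopulation's block plus jitter."""
    missing = set(cells["subpop"]) - set(layout.region_blocks)
    if missing:
        raise ValueError(f"no spatial block for subpopulations {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = cells.copy()
    n = len(cells)
    x = np.empty(n)
    y = np.empty(n)
    for s, (x0, x1, y0, y1) in layout.region_blocks.items():
        mask = (cells["subpop"] == s).to_numpy()
        k = int(mask.sum())
        x[mask] = rng.uniform(x0, x1, size=k)
        y[mask] = rng.uniform(y0, y1, size=k)
    if layout.jitter_sd > 0:
        x += rng.normal(0.0, layout.jitter_sd, size=n)
        y += rng.normal(0.0, layout.jitter_sd, size=n)
    cells["x"] = x
    cells["y"] = y
    return cells


def assign_z_and_volume(cells: pd.DataFrame, zv: ZVolumeConfig, seed: int = 0) -> pd.DataFrame:
    """Draw Z-centers and strictly positive volumes per cell.

    Volumes are normal draws rejection-resampled until positive, preserving
    the configured location/scale while enforcing physicality.
    """
    missing = set(cells["subpop"]) - set(zv.z_mean_by_subpop)
    if missing:
        raise ValueError(f"no z mean configured for subpopulations {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = cells.copy()
    z_mean = cells["subpop"].map(zv.z_mean_by_subpop).to_numpy(dtype=float)
    cells["z_center"] = rng.normal(z_mean, zv.z_sd)
    n = len(cells)
    volume = rng.normal(zv.volume_mean, zv.volume_sd, size=n)
    while np.any(volume <= 0):
        bad = volume <= 0
        volume[bad] = rng.normal(zv.volume_mean, zv.volume_sd, size=int(bad.sum()))
    cells["volume"] = volume
    cells["area"] = np.pi * sphere_radius(volume) ** 2  # equatorial cross-section
    return cells


def sphere_radius(volume: np.ndarray | float) -> np.ndarray | float:
    """Radius of a sphere with the given volume."""
    return (3.0 * np.asarray(volume) / (4.0 * np.pi)) ** (1.0 / 3.0)


def simulate_dataset(config: SimConfig,
                     layout: SpatialLayout | None = None,
                     zv: ZVolumeConfig | None = None,
                     couple_library_to_volume: bool = False) -> SimResult:
    """Full synthetic dataset: counts, positions, Z-centers and volumes.

    Stage seeds are split deterministically from ``config.seed``. With
    ``couple_library_to_volume`` each cell's library factor is additionally
    scaled by volume / mean volume, so transcript content tracks cell size
    (the regime where volume normalization is meaningful).
    """
    sub_seeds = np.random.SeedSequence(config.seed).spawn(6)
    pos_seed = sub_seeds[4].generate_state(1)[0]
    zv_seed = sub_seeds[5].generate_state(1)[0]
    sizes = _largest_remainder_counts(np.asarray(config.subpop_proportions, float),
                                      config.n_cells)
    cells = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(config.n_cells)],
        "subpop": np.repeat(config.subpops, sizes),
    })
    if layout is None:
        layout = SpatialLayout.side_by_side(config.subpops)
    cells = assign_positions(cells, layout, seed=int(pos_seed))
    if zv is None:
        means = dict(zip(config.subpops,
                         np.linspace(4.839, 12.0, len(config.subpops))))
        zv = ZVolumeConfig(z_mean_by_subpop=means)
    cells = assign_z_and_volume(cells, zv, seed=int(zv_seed))
    multiplier = None
    if couple_library_to_volume:
        vol = cells["volume"].to_numpy()
        multiplier = vol / vol.mean()
    result = simulate_counts(config, lib_multiplier=multiplier)
    return SimResult(result.counts, cells, result.de_genes)
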