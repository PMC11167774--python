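"""End-to-end orchestration: simulate, build panels, normalize, compare.

``run_evaluation`` drives the main benchmark (panels x methods -> factors,
normalized matrices, DE tables, concordance reports, optional SVG results).
``run_panel_size_sweep`` measures how panel skew and factor separation decay
with panel size; ``run_capture_study`` measures how normalization of
partially captured counts affects subpopulation separability.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import io as srtio
from .capture import CaptureConfig, apply_capture, capture_table
from .concordance import ConcordanceReport, build_report
from .core import CountMatrix, NormalizedMatrix, align_cells
from .de import run_de
from .normalization import (ScalingFactors, compute_factors, filter_zero_cells,
                            normalize, pearson_residual_normalize,
                            rescale_unit_mean)
from .panels import (GenePanel, compute_skew, full_panel, identify_de_pool,
                     sample_random_panel, sample_skewed_panel, top_k_panel)
from .svg import run_svg, svg_error_rates
from .synthetic import SimConfig, SpatialLayout, ZVolumeConfig, simulate_dataset

logger = logging.getLogger(__name__)

FACTOR_METHODS = ("none", "library_size", "poscounts", "tmm", "volume", "area")
ALL_METHODS = FACTOR_METHODS + ("pearson",)


@dataclass
class RunConfig:
    """Structured configuration of one evaluation run."""

    seed: int = 0
    outdir: str = "srtnorm_out"
    synthetic: dict[str, Any] = field(default_factory=dict)
    input_counts: str | None = None
    input_cells: str | None = None
    skew_subpops: list[str] = field(default_factory=list)
    panel_size: int = 100
    random_panel: bool = True
    methods: tuple[str, ...] = ("none", "library_size", "poscounts", "tmm", "volume")
    alpha: float = 0.05
    lfc_min: float = 0.25
    pool_methods: tuple[str, ...] = ("none", "library_size")
    svg_enabled: bool = False
    svg_bin_size: float = 50.0
    svg_n_perm: int = 999
    svg_k: int = 6
    svg_methods: tuple[str, ...] | None = None
    capture: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unsupported normalization methods: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        for key in ("methods", "pool_methods", "svg_methods"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def load_dataset(config: RunConfig):
    """Dataset from files if paths are given, else seeded synthetic."""
    if config.input_counts:
        counts = srtio.read_counts(config.input_counts)
        cells = srtio.read_cell_table(config.input_cells)
        return counts, align_cells(counts, cells), {}
    sim_kwargs = dict(config.synthetic)
    sim_kwargs.setdefault("seed", config.seed)
    if "subpop_proportions" in sim_kwargs:
        sim_kwargs["subpop_proportions"] = tuple(sim_kwargs["subpop_proportions"])
    couple = sim_kwargs.pop("couple_library_to_volume", False)
    zv_kwargs = {k: sim_kwargs.pop(k) for k in
                 ("z_mean_by_subpop", "z_sd", "volume_mean", "volume_sd")
                 if k in sim_kwargs}
    zv = ZVolumeConfig(**zv_kwargs) if zv_kwargs else None
    sim = simulate_dataset(SimConfig(**sim_kwargs), zv=zv,
                           couple_library_to_volume=couple)
    return sim.counts, sim.cells, sim.de_genes


def _normalized(counts: CountMatrix, method: str, cells: pd.DataFrame,
                panel: str) -> tuple[NormalizedMatrix, ScalingFactors | None]:
    if method == "pearson":
        return pearson_residual_normalize(counts, panel=panel), None
    factors = compute_factors(counts, method, cells=cells)
    return normalize(counts, factors, panel=panel), factors


def build_panels(counts: CountMatrix, cells: pd.DataFrame, config: RunConfig
                 ) -> dict[str, GenePanel]:
    """Full panel plus requested skewed and random panels."""
    panels = {"full": full_panel(counts)}
    if config.skew_subpops:
        retained, _ = filter_zero_cells(counts)
        pools = identify_de_pool(retained, cells, methods=config.pool_methods,
                                 alpha=config.alpha, lfc_min=config.lfc_min)
        seeds = np.random.SeedSequence(config.seed).spawn(len(config.skew_subpops) + 1)
        for i, subpop in enumerate(config.skew_subpops):
            seed = int(seeds[i].generate_state(1)[0])
            panels[f"skewed:{subpop}"] = sample_skewed_panel(
                pools[subpop], config.panel_size, seed, subpop)
        if config.random_panel:
            seed = int(seeds[-1].generate_state(1)[0])
            panels["random"] = sample_random_panel(
                list(counts.gene_ids), config.panel_size, seed)
    return panels


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_evaluation(config: RunConfig, write: bool = True) -> dict[str, Any]:
    """Main benchmark. Returns (and optionally writes) the full report bundle."""
    counts, cells, de_truth = load_dataset(config)
    panels = build_panels(counts, cells, config)

    # Cell matching: keep only cells with positive totals on every panel so
    # every cross-panel comparison is computed on identical cells.
    retained_ids = set(counts.cell_ids)
    for panel in panels.values():
        sub, _ = filter_zero_cells(panel.subset(counts))
        retained_ids &= set(sub.cell_ids)
    retained = [c for c in counts.cell_ids if c in retained_ids]
    census = {"n_cells_total": counts.n_cells, "n_cells_retained": len(retained)}
    logger.info("retained %d/%d cells across all panels", len(retained), counts.n_cells)

    results: dict[str, Any] = {"panels": {}, "census": census}
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    factors_by: dict[tuple[str, str], ScalingFactors | None] = {}
    norms_by: dict[tuple[str, str], NormalizedMatrix] = {}
    svg_by: dict[tuple[str, str], pd.DataFrame] = {}
    svg_methods = config.svg_methods if config.svg_methods is not None else config.methods

    for pname, panel in panels.items():
        sub = panel.subset(counts).subset_cells(retained)
        skew = compute_skew(sub, cells)
        results["panels"][pname] = {
            "provenance": panel.provenance, "size": panel.size,
            "skew": skew.skew,
        }
        for method in config.methods:
            norm, factors = _normalized(sub, method, cells, panel=pname)
            de = run_de(norm, cells)
            key = (pname, method)
            de_tables[key] = de
            factors_by[key] = factors
            norms_by[key] = norm
            if config.svg_enabled and method in svg_methods:
                svg_by[key] = run_svg(norm, cells, bin_size=config.svg_bin_size,
                                      n_perm=config.svg_n_perm, seed=config.seed,
                                      k=config.svg_k)

    reports: list[ConcordanceReport] = []
    svg_rows = []
    for pname in panels:
        if pname == "full":
            continue
        for method in config.methods:
            rep = build_report(
                pname, method,
                de_tables[(pname, method)], de_tables[("full", method)],
                factors_by[(pname, method)], factors_by[("full", method)],
                norms_by[(pname, method)], norms_by[("full", method)],
                alpha=config.alpha)
            reports.append(rep)
            if (pname, method) in svg_by:
                rates = svg_error_rates(svg_by[(pname, method)],
                                        svg_by[("full", method)], alpha=config.alpha)
                svg_rows.append({"panel": pname, "method": method, **rates})

    concordance = pd.concat([r.to_rows() for r in reports], ignore_index=True) \
        if reports else pd.DataFrame(columns=["panel", "method", "metric", "value", "defined"])
    svg_summary = pd.DataFrame(svg_rows)
    results["concordance"] = concordance
    results["svg_summary"] = svg_summary
    results["de_tables"] = de_tables
    results["factors"] = factors_by
    results["normalized"] = norms_by
    results["svg_tables"] = svg_by
    results["reports"] = reports
    results["de_truth"] = de_truth
    results["cells"] = cells

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        factor_frames = []
        for (pname, method), factors in factors_by.items():
            if factors is None:
                continue
            frame = factors.to_frame()
            frame.insert(2, "panel", pname)
            factor_frames.append(frame)
        if factor_frames:
            path = outdir / "factors.csv"
            pd.concat(factor_frames, ignore_index=True).to_csv(path, index=False)
            written.append(path)
        de_frames = []
        for (pname, method), de in de_tables.items():
            de = de.copy()
            de["panel"] = pname
            de["method"] = method
            de_frames.append(de)
        path = outdir / "de_results.csv"
        pd.concat(de_frames, ignore_index=True).to_csv(path, index=False)
        written.append(path)
        path = outdir / "concordance.csv"
        concordance.to_csv(path, index=False)
        written.append(path)
        if len(svg_summary):
            path = outdir / "svg_summary.csv"
            svg_summary.to_csv(path, index=False)
            written.append(path)
        manifest = {
            "seed": config.seed,
            "panels": {p: results["panels"][p] for p in results["panels"]},
            "census": census,
            "files": {p.name: _sha256(p) for p in written},
        }
        (outdir / "report.json").write_text(json.dumps(manifest, indent=2))
        logger.info("wrote %d output files to %s", len(written) + 1, outdir)
    return results


# ---------------------------------------------------------------------------
# Panel-size sweep

def run_panel_size_sweep(config: RunConfig,
                         sizes: tuple[int, ...] = (50, 100, 500, 1000, 5000),
                         target_subpop: str | None = None) -> pd.DataFrame:
    """Skew, factor separation, and concordance for top-k panels of each size.

    Sizes above the gene count are capped at it; size == n_genes reproduces
    the full panel.
    """
    counts, cells, _ = load_dataset(config)
    retained, _ = filter_zero_cells(counts)
    cells = cells[cells["cell_id"].isin(retained.cell_ids)]
    if target_subpop is None:
        target_subpop = sorted(cells["subpop"].unique())[0]
    norm_full, sf_full = _normalized(retained, "library_size", cells, "full")
    de_full = run_de(norm_full, cells)
    labels = cells.set_index("cell_id").loc[retained.cell_ids, "subpop"].to_numpy()
    in_target = labels == target_subpop
    rows = []
    for size in sizes:
        k = min(size, retained.n_genes)
        panel = top_k_panel(de_full, target_subpop, k)
        sub = panel.subset(retained)
        sub_nz, _ = filter_zero_cells(sub)
        shared_cells = [c for c in retained.cell_ids if c in set(sub_nz.cell_ids)]
        sub = sub.subset_cells(shared_cells)
        skew = compute_skew(sub, cells)
        norm_p, sf_p = _normalized(sub, "library_size", cells, f"topk:{k}")
        unit = rescale_unit_mean(sf_p).factors
        mask = np.isin(np.array(sub.cell_ids), np.array(retained.cell_ids)[in_target])
        separation = float(unit[mask].mean() / unit[~mask].mean())
        de_p = run_de(norm_p, cells)
        full_matched = de_full[de_full["gene"].isin(panel.gene_ids)]
        rep = build_report(f"topk:{k}", "library_size", de_p, full_matched,
                           sf_p, None, alpha=config.alpha)
        rows.append({
            "requested_size": size, "size": k, "skew": skew.skew,
            "factor_separation": separation,
            "fpr": rep.fpr, "fnr": rep.fnr, "spr": rep.spr, "snr": rep.snr,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Capture study

def _pca_embedding(norm: NormalizedMatrix, n_components: int = 50,
                   seed: int = 0) -> np.ndarray:
    """log10(x+1), per-gene centering and scaling, then PCA across cells."""
    x = np.log10(norm.values + 1.0).T  # cells x genes
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_components = min(n_components, x.shape[1], x.shape[0] - 1)
    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def subpopulation_separability(norm: NormalizedMatrix, cells: pd.DataFrame,
                               n_components: int = 50, seed: int = 0) -> float:
    """Silhouette of subpopulation labels in 50-dimensional PC space."""
    labels = cells.set_index("cell_id").loc[norm.cell_ids, "subpop"].to_numpy()
    emb = _pca_embedding(norm, n_components=n_components, seed=seed)
    return float(silhouette_score(emb, labels))


def run_capture_study(config: RunConfig,
                      methods: tuple[str, ...] = ("none", "library_size",
                                                  "poscounts", "volume")) -> dict[str, Any]:
    """Partial-capture simulation and separability across normalizations.

    Captured counts use the captured volume (volume x captured fraction) as
    the volume scaling factor; ground-truth counts use the full volume.
    """
    counts, cells, _ = load_dataset(config)
    cap_kwargs = dict(config.capture)
    mode = cap_kwargs.pop("mode", "scale")
    cap_cfg = CaptureConfig(**cap_kwargs)
    table = capture_table(cells, cap_cfg)
    fractions = table["captured_fraction"].to_numpy()
    captured = apply_capture(counts, fractions, mode=mode, seed=config.seed)

    cells_cap = cells.copy()
    cells_cap["volume"] = table["captured_volume"].to_numpy()
    keep = cells_cap["volume"] > 0
    kept_ids = [c for c, k in zip(counts.cell_ids, keep) if k]
    captured = captured.subset_cells(kept_ids)
    captured, _ = filter_zero_cells(captured)
    kept_ids = list(captured.cell_ids)
    cells_cap = cells_cap[cells_cap["cell_id"].isin(kept_ids)]
    truth = counts.subset_cells(kept_ids)
    cells_truth = cells[cells["cell_id"].isin(kept_ids)]

    separability = {"captured": {}, "truth": {}}
    for method in methods:
        norm_c, _ = _normalized(captured, method, cells_cap, "captured")
        separability["captured"][method] = subpopulation_separability(
            norm_c, cells_cap, seed=config.seed)
        norm_t, _ = _normalized(truth, method, cells_truth, "truth")
        separability["truth"][method] = subpopulation_separability(
            norm_t, cells_truth, seed=config.seed)
    group_census = table.groupby("group").size().to_dict()
    return {
        "separability": separability,
        "capture_table": table,
        "group_census": group_census,
        "captured_counts": captured,
        "cells_captured": cells_cap,
    }
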