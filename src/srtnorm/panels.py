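"""Gene panel construction and panel-skew quantification.

Skewed panels sample from the pool of genes significantly enriched in one
subpopulation; random panels sample from all genes; top-k panels take the k
most significant genes for a subpopulation. Panel skew is the KL divergence
between the subpopulation shares of detected counts and of cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CountMatrix
from .de import LFC_OK, run_de
from .normalization import compute_factors, normalize, filter_zero_cells


@dataclass(frozen=True)
class GenePanel:
    """Ordered unique gene subset with provenance tag."""

    gene_ids: tuple[str, ...]
    provenance: str  # full | skewed:<subpop> | random | topk:<k>
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("panel gene ids must be unique")

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    def subset(self, counts: CountMatrix) -> CountMatrix:
        return counts.subset_genes(list(self.gene_ids))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("\n".join(self.gene_ids) + "\n")
        header = {"provenance": self.provenance, "size": self.size, "seed": self.seed}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "GenePanel":
        path = Path(path)
        genes = tuple(path.read_text().split())
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(genes, meta.get("provenance", "unknown"), meta.get("seed"))


def full_panel(counts: CountMatrix) -> GenePanel:
    return GenePanel(tuple(counts.gene_ids), "full")


@dataclass
class SkewScore:
    """KL divergence of count shares from cell shares across subpopulations."""

    skew: float
    p_counts: pd.Series
    q_cells: pd.Series


def compute_skew(counts: CountMatrix, cells: pd.DataFrame) -> SkewScore:
    """Skew = sum_i P_i ln(P_i / Q_i), in nats; zero-count terms contribute 0."""
    labels = cells.set_index("cell_id").loc[counts.cell_ids, "subpop"]
    totals = counts.cell_totals()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("total detected counts must be positive")
    by_subpop = pd.Series(totals, index=labels.to_numpy()).groupby(level=0).sum()
    p = by_subpop / grand
    q = labels.value_counts().sort_index() / len(labels)
    p = p.reindex(q.index, fill_value=0.0)
    if ((q <= 0) & (p > 0)).any():
        raise ValueError("a subpopulation with counts has no cells")
    nonzero = p > 0
    skew = float(np.sum(p[nonzero] * np.log(p[nonzero] / q[nonzero])))
    return SkewScore(skew, p, q)


def identify_de_pool(counts: CountMatrix, cells: pd.DataFrame,
                     methods: tuple[str, ...] = ("none", "library_size"),
                     alpha: float = 0.05, lfc_min: float = 0.25,
                     de_tables: dict[str, pd.DataFrame] | None = None
                     ) -> dict[str, set[str]]:
    """Per-subpopulation pools of genes significant under ANY normalization.

    A gene joins subpopulation A's pool if, under at least one of the
    requested normalizations (or no normalization), its A-vs-rest adjusted p
    is below ``alpha`` and its |log2 fold change| exceeds ``lfc_min``.
    Precomputed DE tables can be passed to skip recomputation.
    """
    if de_tables is None:
        de_tables = {}
        retained, _ = filter_zero_cells(counts)
        for method in methods:
            factors = compute_factors(retained, method, cells=cells)
            norm = normalize(retained, factors)
            de_tables[method] = run_de(norm, cells)
    pools: dict[str, set[str]] = {}
    for method, table in de_tables.items():
        ok = (table["lfc_flag"] == LFC_OK)
        hits = table[ok & (table["p_adj"] < alpha) & (table["lfc"].abs() > lfc_min)]
        for subpop, group in hits.groupby("region"):
            pools.setdefault(str(subpop), set()).update(group["gene"])
    for subpop in pd.unique(cells["subpop"]):
        pools.setdefault(str(subpop), set())
    return pools


def sample_skewed_panel(pool: set[str], k: int, seed: int, subpop: str) -> GenePanel:
    """Uniform sample of k genes from a subpopulation's enriched pool."""
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} genes is smaller than k={k}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(sorted(pool), size=k, replace=False)
    return GenePanel(tuple(chosen), f"skewed:{subpop}", seed=seed)


def sample_random_panel(all_genes: list[str], k: int, seed: int) -> GenePanel:
    """Uniform sample of k genes from the full gene universe."""
    if len(all_genes) < k:
        raise ValueError(f"universe of {len(all_genes)} genes is smaller than k={k}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(list(all_genes), size=k, replace=False)
    return GenePanel(tuple(chosen), "random", seed=seed)


def top_k_panel(de_results: pd.DataFrame, subpop: str, k: int) -> GenePanel:
    """The k most significant genes for one subpopulation-vs-rest comparison.

    Ties in adjusted p are broken by larger |LFC|, then lexical gene id.
    """
    table = de_results[de_results["region"] == subpop].copy()
    if table.empty:
        raise ValueError(f"no DE results for subpopulation {subpop!r}")
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} genes with results")
    abs_lfc = table["lfc"].abs()
    abs_lfc = abs_lfc.where(np.isfinite(abs_lfc), np.inf)
    table["_abs_lfc"] = abs_lfc.fillna(0.0)
    table = table.sort_values(["p_adj", "_abs_lfc", "gene"],
                              ascending=[True, False, True], kind="mergesort")
    return GenePanel(tuple(table["gene"].head(k)), f"topk:{k}")
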