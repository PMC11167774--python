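"""One-region-vs-rest differential expression and fold change.

The test is a one-sided Wilcoxon rank-sum ("greater in region"), using a
tie-corrected, continuity-corrected normal approximation when both groups
have at least 20 cells and exact enumeration below that. P-values are
Benjamini-Hochberg adjusted per region-vs-rest family. Log2 fold change is
the ratio of arithmetic means of normalized expression, with undefined and
infinite cases flagged rather than patched.
"""
from __future__ import annotations

from itertools import combinations
from math import comb, inf, nan

import numpy as np
import pandas as pd
from scipy import stats

from .core import NormalizedMatrix

EXACT_MAX_GROUP = 20          # below this per-group size, enumerate exactly
_EXACT_ENUM_LIMIT = 200_000   # max C(n, n_A) for brute-force enumeration with ties

LFC_OK = "ok"
LFC_POS_INF = "infinite"
LFC_UNDEFINED = "undefined"


def rank_sum_greater(values: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-sided rank-sum test per row (alternative: group greater).

    Returns (U statistic of the group, one-sided p) with midranks, tie
    variance correction and 0.5 continuity correction.
    """
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    n = n1 + n2
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per row
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var_u)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - mean_u - 0.5) / np.where(sd > 0, sd, 1.0)
    p = stats.norm.sf(z)
    p = np.where(sd > 0, p, 1.0)  # all values tied: no evidence
    return u, p


def wilcoxon_exact_greater(group: np.ndarray, rest: np.ndarray) -> tuple[float, float]:
    """Exact one-sided rank-sum p by enumeration (small samples).

    Without ties the null distribution of the rank sum is built by dynamic
    programming; with ties, all C(n, n1) assignments of the midranks are
    enumerated (guarded by a size limit).
    """
    group = np.asarray(group, dtype=float)
    rest = np.asarray(rest, dtype=float)
    n1, n2 = len(group), len(rest)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([group, rest])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    if not has_ties:
        # exact null distribution of the rank sum over {1..n} choose n1,
        # built by dynamic programming over (#chosen, sum)
        table = np.zeros((n1 + 1, int(n * (n + 1) / 2) + 1))
        table[0, 0] = 1.0
        for k in range(1, n + 1):
            for j in range(min(k, n1), 0, -1):
                table[j, k:] += table[j - 1, :-k]
        total = comb(n, n1)
        sums = np.arange(table.shape[1])
        p = table[n1, sums >= r1].sum() / total
        return float(u), float(p)
    if comb(n, n1) > _EXACT_ENUM_LIMIT:
        vals = pooled[None, :]
        mask = np.zeros(n, dtype=bool)
        mask[:n1] = True
        _, p = rank_sum_greater(vals, mask)
        return float(u), float(p[0])
    count_ge = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if ranks[list(idx)].sum() >= r1:
            count_ge += 1
    return float(u), count_ge / total


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def log2_fold_change(norm: NormalizedMatrix, in_group: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Per-gene log2 ratio of arithmetic means (group vs rest), with flags."""
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() == 0 or (~in_group).sum() == 0:
        raise ValueError("both groups must be nonempty")
    mean_a = norm.values[:, in_group].mean(axis=1)
    mean_rest = norm.values[:, ~in_group].mean(axis=1)
    lfc = np.full(norm.n_genes, nan)
    flags = []
    for g in range(norm.n_genes):
        if mean_rest[g] > 0 and mean_a[g] > 0:
            lfc[g] = np.log2(mean_a[g] / mean_rest[g])
            flags.append(LFC_OK)
        elif mean_rest[g] == 0 and mean_a[g] > 0:
            lfc[g] = inf
            flags.append(LFC_POS_INF)
        elif mean_rest[g] > 0 and mean_a[g] == 0:
            lfc[g] = -inf
            flags.append(LFC_POS_INF)
        else:
            flags.append(LFC_UNDEFINED)
    return lfc, flags


def wilcoxon_region_vs_rest(norm: NormalizedMatrix, cells: pd.DataFrame,
                            subpop: str) -> pd.DataFrame:
    """One-sided rank-sum test of every gene for one region vs the rest."""
    labels = cells.set_index("cell_id").loc[norm.cell_ids, "subpop"].to_numpy()
    in_group = labels == subpop
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"subpopulation {subpop!r} or its complement is empty")
    if min(n1, n2) >= EXACT_MAX_GROUP:
        u, p = rank_sum_greater(norm.values, in_group)
    else:
        u = np.empty(norm.n_genes)
        p = np.empty(norm.n_genes)
        for g in range(norm.n_genes):
            u[g], p[g] = wilcoxon_exact_greater(norm.values[g, in_group],
                                                norm.values[g, ~in_group])
    return pd.DataFrame({"gene": norm.gene_ids, "u_stat": u, "p": p,
                         "n_A": n1, "n_rest": n2})


def run_de(norm: NormalizedMatrix, cells: pd.DataFrame,
           subpops: list[str] | None = None,
           bh_family: str = "per_region") -> pd.DataFrame:
    """Full DE table over genes x subpopulations with p, adjusted p and LFC."""
    labels = cells.set_index("cell_id").loc[norm.cell_ids, "subpop"].to_numpy()
    if subpops is None:
        subpops = sorted(pd.unique(labels))
    if len(subpops) < 2 and len(pd.unique(labels)) < 2:
        raise ValueError("need at least two subpopulations")
    frames = []
    for s in subpops:
        tab = wilcoxon_region_vs_rest(norm, cells, s)
        lfc, flags = log2_fold_change(norm, labels == s)
        tab["region"] = s
        tab["lfc"] = lfc
        tab["lfc_flag"] = flags
        if bh_family == "per_region":
            tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    if bh_family == "global":
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    elif bh_family != "per_region":
        raise ValueError("bh_family must be 'per_region' or 'global'")
    cols = ["gene", "region", "u_stat", "p", "p_adj", "lfc", "lfc_flag", "n_A", "n_rest"]
    return out[cols]
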