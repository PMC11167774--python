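"""Shared fixtures.

The heavyweight fixtures are session-scoped: one seeded bias-reproduction
dataset (2000 cells, 500 genes, two subpopulations, strong A-enrichment,
100-gene A-skewed panel) reused by the acceptance suite and several unit
tests, plus a small dataset for fast end-to-end checks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from srtnorm.core import CountMatrix
from srtnorm.de import run_de
from srtnorm.normalization import filter_zero_cells, library_size_factors, rescale_unit_mean
from srtnorm.panels import full_panel, identify_de_pool, sample_random_panel, sample_skewed_panel
from srtnorm.pipeline import _normalized
from srtnorm.synthetic import SimConfig, simulate_dataset

BIAS_SIM_CONFIG = dict(
    n_genes=500, n_cells=2000, subpop_proportions=(0.5, 0.5),
    de_prob=0.25, de_fc_location=1.5, de_fc_scale=0.6, seed=7,
)
BIAS_PANEL_SIZE = 100
BIAS_PANEL_SEED = 11


@pytest.fixture(scope="session")
def bias_fixture():
    """Strongly A-skewed 100-gene panel on a 2-subpopulation dataset."""
    sim = simulate_dataset(SimConfig(**BIAS_SIM_CONFIG))
    retained, _ = filter_zero_cells(sim.counts)
    pools = identify_de_pool(retained, sim.cells, methods=("none", "library_size"))
    skewed = sample_skewed_panel(pools["A"], BIAS_PANEL_SIZE, BIAS_PANEL_SEED, "A")
    random_panel = sample_random_panel(list(retained.gene_ids), BIAS_PANEL_SIZE, BIAS_PANEL_SEED)

    sub = skewed.subset(retained)
    sub_nz, _ = filter_zero_cells(sub)
    shared = [c for c in retained.cell_ids if c in set(sub_nz.cell_ids)]
    sub = sub.subset_cells(shared)
    full = retained.subset_cells(shared)
    labels = sim.cells.set_index("cell_id").loc[shared, "subpop"].to_numpy()

    runs = {}
    for method in ("library_size", "volume"):
        norm_s, sf_s = _normalized(sub, method, sim.cells, "skewed")
        norm_f, sf_f = _normalized(full, method, sim.cells, "full")
        runs[method] = {
            "norm_skewed": norm_s, "norm_full": norm_f,
            "sf_skewed": sf_s, "sf_full": sf_f,
            "de_skewed": run_de(norm_s, sim.cells),
            "de_full": run_de(norm_f, sim.cells),
        }
    return {
        "sim": sim, "cells": sim.cells, "pools": pools,
        "skewed_panel": skewed, "random_panel": random_panel,
        "full_counts": full, "skewed_counts": sub,
        "retained_cells": shared, "labels": labels,
        "in_A": labels == "A", "runs": runs,
    }


@pytest.fixture(scope="session")
def small_sim():
    """Fast 120-gene x 300-cell dataset with 2 subpopulations."""
    return simulate_dataset(SimConfig(
        n_genes=120, n_cells=300, subpop_proportions=(0.5, 0.5),
        de_prob=0.2, de_fc_location=1.3, de_fc_scale=0.5, seed=3))


@pytest.fixture()
def toy_counts():
    """The worked poscounts example matrix."""
    return CountMatrix(np.array([[2.0, 4.0], [4.0, 8.0], [6.0, 12.0]]),
                       ["g1", "g2", "g3"], ["c1", "c2"])


@pytest.fixture()
def two_subpop_cells():
    def make(cell_ids, labels, volume=None):
        df = pd.DataFrame({"cell_id": cell_ids, "subpop": labels})
        if volume is not None:
            df["volume"] = volume
        return df
    return make
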