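import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from srtnorm.synthetic import (SimConfig, SpatialLayout, ZVolumeConfig,
                               assign_positions, assign_z_and_volume,
                               simulate_counts, simulate_dataset, sphere_radius)


class TestSimConfig:
    def test_rejects_tiny_dimensions(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=1, n_cells=100)
        with pytest.raises(ValueError):
            SimConfig(n_genes=100, n_cells=1)

    def test_rejects_bad_de_prob(self):
        with pytest.raises(ValueError):
            SimConfig(de_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(de_prob=-0.1)

    def test_rejects_unnormalized_proportions(self):
        with pytest.raises(ValueError):
            SimConfig(subpop_proportions=(0.5, 0.4))

    def test_rejects_nonpositive_scales(self):
        with pytest.raises(ValueError):
            SimConfig(mean_shape=0.0)


class TestSimulateCounts:
    def test_same_seed_bitwise_identical(self):
        a = simulate_counts(SimConfig(n_genes=40, n_cells=100, seed=5))
        b = simulate_counts(SimConfig(n_genes=40, n_cells=100, seed=5))
        assert np.array_equal(a.counts.values, b.counts.values)
        assert a.de_genes == b.de_genes

    def test_different_seed_differs(self):
        a = simulate_counts(SimConfig(n_genes=40, n_cells=100, seed=5))
        b = simulate_counts(SimConfig(n_genes=40, n_cells=100, seed=6))
        assert not np.array_equal(a.counts.values, b.counts.values)

    def test_counts_are_integers(self):
        sim = simulate_counts(SimConfig(n_genes=40, n_cells=100, seed=5))
        assert np.array_equal(sim.counts.values, np.round(sim.counts.values))
        assert np.all(sim.counts.values >= 0)

    def test_no_de_means_subpop_means_agree(self):
        # de_prob=0: per-gene subpopulation means should differ by less than
        # 3 Monte Carlo standard errors for >= 95% of genes.
        sim = simulate_counts(SimConfig(n_genes=300, n_cells=2000, de_prob=0.0,
                                        subpop_proportions=(0.5, 0.5), seed=9))
        v = sim.counts.values
        in_a = (sim.cells["subpop"] == "A").to_numpy()
        mean_a, mean_b = v[:, in_a].mean(axis=1), v[:, ~in_a].mean(axis=1)
        se = np.sqrt(v[:, in_a].var(axis=1) / in_a.sum()
                     + v[:, ~in_a].var(axis=1) / (~in_a).sum())
        se[se == 0] = np.inf
        frac_ok = np.mean(np.abs(mean_a - mean_b) < 3 * se)
        assert frac_ok >= 0.95

    def test_lib_location_doubles_totals(self):
        # closed form: expected cell total scales as exp(lib_location)
        base = SimConfig(n_genes=200, n_cells=1500, de_prob=0.0, seed=4)
        doubled = SimConfig(n_genes=200, n_cells=1500, de_prob=0.0, seed=4,
                            lib_location=base.lib_location + math.log(2.0))
        t1 = simulate_counts(base).counts.cell_totals().mean()
        t2 = simulate_counts(doubled).counts.cell_totals().mean()
        assert t2 / t1 == pytest.approx(2.0, rel=0.05)

    def test_de_ground_truth_fold_change(self):
        # genes flagged DE for A show a simulated mean fold change matching
        # their drawn factor within Monte Carlo error
        sim = simulate_counts(SimConfig(n_genes=200, n_cells=4000, de_prob=0.1,
                                        de_fc_location=1.2, de_fc_scale=0.3,
                                        subpop_proportions=(0.5, 0.5), seed=21))
        v = sim.counts.values
        in_a = (sim.cells["subpop"] == "A").to_numpy()
        gene_pos = {g: i for i, g in enumerate(sim.counts.gene_ids)}
        b_de = set(sim.de_genes["B"])
        checked = 0
        for gene, factor in sim.de_genes["A"].items():
            if gene in b_de:
                continue  # confounded by B's own enrichment
            i = gene_pos[gene]
            ma, mb = v[i, in_a].mean(), v[i, ~in_a].mean()
            if mb < 0.05:  # too sparse for a stable ratio
                continue
            se_ratio = 3 * np.sqrt(v[i, in_a].var() / in_a.sum()) / mb \
                + 3 * ma * np.sqrt(v[i, ~in_a].var() / (~in_a).sum()) / mb ** 2
            assert abs(ma / mb - factor) < se_ratio + 0.25
            checked += 1
        assert checked > 5

    def test_lib_multiplier_scales_cells(self):
        cfg = SimConfig(n_genes=200, n_cells=1000, de_prob=0.0, seed=2)
        mult = np.linspace(0.25, 4.0, 1000)
        sim = simulate_counts(cfg, lib_multiplier=mult)
        totals = sim.counts.cell_totals()
        lo, hi = totals[:100].mean(), totals[-100:].mean()
        assert hi / lo == pytest.approx(mult[-50] / mult[50], rel=0.2)

    def test_lib_multiplier_validation(self):
        cfg = SimConfig(n_genes=20, n_cells=10, seed=2)
        with pytest.raises(ValueError):
            simulate_counts(cfg, lib_multiplier=np.ones(5))
        with pytest.raises(ValueError):
            simulate_counts(cfg, lib_multiplier=np.zeros(10))


class TestPositions:
    def test_no_jitter_inside_block(self):
        cells = pd.DataFrame({"cell_id": ["c0"], "subpop": ["A"]})
        layout = SpatialLayout({"A": (0.0, 50.0, 0.0, 50.0)}, jitter_sd=0.0)
        out = assign_positions(cells, layout, seed=0)
        assert 0 <= out.loc[0, "x"] <= 50 and 0 <= out.loc[0, "y"] <= 50

    def test_disjoint_blocks_separable(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(100)],
                              "subpop": ["A"] * 50 + ["B"] * 50})
        layout = SpatialLayout({"A": (0, 100, 0, 100), "B": (200, 300, 0, 100)})
        out = assign_positions(cells, layout, seed=1)
        assert out.loc[out.subpop == "A", "x"].max() < out.loc[out.subpop == "B", "x"].min()

    def test_reproducible(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(20)],
                              "subpop": ["A"] * 20})
        layout = SpatialLayout({"A": (0, 10, 0, 10)}, jitter_sd=2.0)
        a = assign_positions(cells, layout, seed=7)
        b = assign_positions(cells, layout, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_block_raises(self):
        cells = pd.DataFrame({"cell_id": ["c0"], "subpop": ["Z"]})
        layout = SpatialLayout({"A": (0, 10, 0, 10)})
        with pytest.raises(ValueError, match="Z"):
            assign_positions(cells, layout, seed=0)

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            SpatialLayout({"A": (0, 0, 0, 10)})


class TestZVolume:
    def _cells(self, n, subpop="A"):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                             "subpop": [subpop] * n})

    def test_z_mean_matches_configured(self):
        # empirical mean z within 3*(1.5/sqrt(n)) of 4.839 um
        n = 2000
        out = assign_z_and_volume(self._cells(n), ZVolumeConfig(), seed=13)
        assert abs(out["z_center"].mean() - 4.839) < 3 * 1.5 / np.sqrt(n)

    def test_volumes_strictly_positive(self):
        out = assign_z_and_volume(self._cells(2000), ZVolumeConfig(), seed=13)
        assert (out["volume"] > 0).all()

    def test_radius_of_unit_millivolume(self):
        # invert the sphere-volume formula numerically as an oracle
        oracle = brentq(lambda r: 4.0 / 3.0 * np.pi * r ** 3 - 1000.0, 0.1, 100.0)
        assert sphere_radius(1000.0) == pytest.approx(oracle, abs=1e-9)
        assert sphere_radius(1000.0) == pytest.approx(6.2035, abs=1e-4)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ZVolumeConfig(z_sd=0.0)
        with pytest.raises(ValueError):
            ZVolumeConfig(volume_mean=-1.0)

    def test_missing_subpop_mean_raises(self):
        with pytest.raises(ValueError):
            assign_z_and_volume(self._cells(5, subpop="Q"), ZVolumeConfig(), seed=0)


class TestSimulateDataset:
    def test_full_dataset_columns_and_determinism(self):
        cfg = SimConfig(n_genes=30, n_cells=60, seed=17)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        for col in ("cell_id", "x", "y", "subpop", "z_center", "volume", "area"):
            assert col in a.cells.columns
        assert np.array_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_volume_coupling_changes_totals(self):
        cfg = SimConfig(n_genes=100, n_cells=500, de_prob=0.0, seed=8,
                        lib_scale=0.05)
        sim = simulate_dataset(cfg, couple_library_to_volume=True)
        totals = sim.counts.cell_totals()
        vol = sim.cells["volume"].to_numpy()
        r = np.corrcoef(totals, vol)[0, 1]
        assert r > 0.8
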