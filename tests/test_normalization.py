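import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srtnorm.core import CountMatrix
from srtnorm.normalization import (filter_zero_cells, library_size_factors,
                                   normalize, pearson_residual_normalize,
                                   poscounts_factors, rescale_unit_mean,
                                   tmm_factors, volume_factors)


def classic_median_of_ratios(v: np.ndarray) -> np.ndarray:
    """Independent oracle: DESeq-style factors on zero-free data."""
    log_geo = np.log(v).mean(axis=1)
    return np.array([np.median(v[:, i] / np.exp(log_geo)) for i in range(v.shape[1])])


def _cm(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return CountMatrix(values, [f"{prefix}{i}" for i in range(values.shape[0])],
                       [f"c{i}" for i in range(values.shape[1])])


class TestLibrarySize:
    def test_column_sum(self):
        cm = _cm([[1.0], [2.0], [3.0]])
        assert library_size_factors(cm).factors[0] == 6.0

    def test_equal_totals_proportional_normalization(self):
        cm = _cm([[1, 2], [2, 1], [3, 3]])
        sf = library_size_factors(cm)
        assert sf.factors[0] == sf.factors[1]
        norm = normalize(cm, sf)
        assert np.allclose(norm.values * sf.factors[0], cm.values)

    def test_zero_total_cell_rejected(self):
        cm = _cm([[1, 0], [1, 0]])
        with pytest.raises(ValueError):
            library_size_factors(cm)

    def test_skewed_panel_inflates_target_factors(self):
        # 2-subpop toy: gene g0 enriched in cells 0-1; an A-skewed panel
        # (g0 only plus a flat gene) raises A's relative factor
        cm = _cm([[20, 20, 2, 2], [5, 5, 5, 5], [3, 3, 3, 3]])
        full = rescale_unit_mean(library_size_factors(cm)).factors
        skewed = rescale_unit_mean(library_size_factors(
            cm.subset_genes(["g0", "g1"]))).factors
        ratio_full = full[:2].mean() / full[2:].mean()
        ratio_skew = skewed[:2].mean() / skewed[2:].mean()
        assert ratio_skew > ratio_full


class TestPoscounts:
    def test_printed_toy_matrix(self, toy_counts):
        sf = poscounts_factors(toy_counts)
        assert sf.factors == pytest.approx([1 / np.sqrt(2), np.sqrt(2)], abs=1e-12)

    def test_doubled_column_ratio(self):
        base = np.array([[2.0], [5.0], [9.0]])
        cm = _cm(np.hstack([base, 2 * base]))
        sf = poscounts_factors(cm)
        assert sf.factors[1] / sf.factors[0] == pytest.approx(2.0, abs=1e-12)

    def test_single_cell_zero_free_is_one(self):
        cm = _cm([[3.0], [7.0], [11.0]])
        with pytest.warns(RuntimeWarning):  # n=1 trips the degeneracy census
            assert poscounts_factors(cm).factors[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_classic_oracle_on_zero_free_data(self):
        rng = np.random.default_rng(4)
        v = rng.poisson(20.0, (40, 15)).astype(float) + 1.0
        cm = _cm(v)
        assert poscounts_factors(cm).factors == pytest.approx(
            classic_median_of_ratios(v), abs=1e-10)

    def test_scale_equivariance_of_relative_factors(self):
        # scaling one cell by c scales its factor relative to any other cell
        # by exactly c (the absolute factor moves by c^((n-1)/n) because the
        # scaled cell also shifts the geometric means)
        rng = np.random.default_rng(5)
        v = rng.poisson(10.0, (30, 8)).astype(float) + 1.0
        scaled = v.copy()
        scaled[:, 3] *= 5.0
        f0 = poscounts_factors(_cm(v)).factors
        f1 = poscounts_factors(_cm(scaled)).factors
        assert (f1[3] / f1[0]) / (f0[3] / f0[0]) == pytest.approx(5.0, rel=1e-9)
        assert f1[3] / f0[3] == pytest.approx(5.0 ** (7 / 8), rel=1e-9)

    def test_degenerate_warning_on_sparse(self):
        rng = np.random.default_rng(6)
        v = (rng.random((100, 20)) < 0.02) * 1.0
        v[0, :] = 1.0  # keep every cell computable
        with pytest.warns(RuntimeWarning, match="degenerate"):
            poscounts_factors(_cm(v))

    def test_all_zero_gene_handled(self):
        cm = _cm([[2, 4], [0, 0], [6, 12]])
        sf = poscounts_factors(cm)
        assert np.all(sf.factors > 0)


class TestTMM:
    def test_identical_cells(self):
        cm = _cm(np.tile([[5.0], [9.0], [2.0]], (1, 2)))
        assert tmm_factors(cm).factors == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_proportional_cells(self):
        cm = _cm([[2, 4], [4, 8], [6, 12]])
        assert tmm_factors(cm).factors == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(7)
        v = rng.poisson(8.0, (60, 12)).astype(float)
        v[:, 0] += 1  # avoid zero totals
        cm = _cm(v + (v.sum(axis=0) == 0))
        # f = 1/factor in the paper convention; geometric mean of f is 1
        f = 1.0 / tmm_factors(cm).factors
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_effective_mode_tracks_library(self):
        base = np.array([[2.0], [5.0], [9.0], [4.0]])
        cm = _cm(np.hstack([base, 3 * base]))
        eff = tmm_factors(cm, convention="effective").factors
        assert eff[1] / eff[0] == pytest.approx(3.0, rel=1e-9)

    def test_singleton_pairing_disjoint_support(self):
        # no gene positive in both cells: wsp fallback must still work
        cm = _cm([[4, 0], [8, 0], [0, 3], [0, 9]])
        sf = tmm_factors(cm)
        assert np.all(sf.factors > 0)

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            tmm_factors(_cm([[1.0], [2.0]]))

    def test_unknown_convention(self):
        cm = _cm([[2, 4], [4, 8]])
        with pytest.raises(ValueError):
            tmm_factors(cm, convention="bogus")


class TestVolume:
    def _cells(self):
        return pd.DataFrame({"cell_id": ["c0", "c1"], "subpop": ["A", "B"],
                             "volume": [10.0, 20.0], "area": [4.0, 8.0]})

    def test_volume_values(self):
        sf = volume_factors(self._cells())
        assert list(sf.factors) == [10.0, 20.0]

    def test_area_values(self):
        sf = volume_factors(self._cells(), use="area")
        assert list(sf.factors) == [4.0, 8.0]

    def test_panel_invariance(self):
        cells = self._cells()
        cm = _cm([[1, 2], [3, 4], [5, 6]])
        sub = cm.subset_genes(["g0"])
        sf_full = volume_factors(cells, cell_ids=list(cm.cell_ids))
        sf_sub = volume_factors(cells, cell_ids=list(sub.cell_ids))
        assert np.array_equal(sf_full.factors, sf_sub.factors)
        n_full = normalize(cm, sf_full)
        n_sub = normalize(sub, sf_sub)
        assert np.array_equal(n_full.values[0], n_sub.values[0])

    def test_nonpositive_volume_rejected(self):
        cells = self._cells()
        cells.loc[0, "volume"] = 0.0
        with pytest.raises(ValueError):
            volume_factors(cells)

    def test_unknown_use(self):
        with pytest.raises(ValueError):
            volume_factors(self._cells(), use="mass")


class TestNormalize:
    def test_unit_factors_identity(self):
        cm = _cm([[1, 2], [3, 4]])
        from srtnorm.normalization import ScalingFactors
        sf = ScalingFactors(list(cm.cell_ids), np.ones(2), "library_size")
        assert np.array_equal(normalize(cm, sf).values, cm.values)

    def test_library_norm_columns_sum_to_one(self):
        rng = np.random.default_rng(8)
        cm = _cm(rng.poisson(5.0, (20, 6)).astype(float) + 1)
        norm = normalize(cm, library_size_factors(cm))
        assert np.allclose(norm.values.sum(axis=0), 1.0)

    def test_simple_division(self):
        cm = _cm([[6.0]])
        from srtnorm.normalization import ScalingFactors
        sf = ScalingFactors(["c0"], np.array([2.0]), "library_size")
        assert normalize(cm, sf).values[0, 0] == 3.0

    def test_factor_validation(self):
        from srtnorm.normalization import ScalingFactors
        with pytest.raises(ValueError):
            ScalingFactors(["c0"], np.array([0.0]), "library_size")
        with pytest.raises(ValueError):
            ScalingFactors(["c0"], np.array([-2.0]), "library_size")


class TestRescaleUnitMean:
    def test_example(self):
        from srtnorm.normalization import ScalingFactors
        sf = ScalingFactors(["a", "b", "c"], np.array([2.0, 4.0, 6.0]), "library_size")
        assert rescale_unit_mean(sf).factors == pytest.approx([0.5, 1.0, 1.5])

    def test_idempotent(self):
        from srtnorm.normalization import ScalingFactors
        sf = ScalingFactors(["a", "b"], np.array([0.5, 1.5]), "library_size")
        once = rescale_unit_mean(sf)
        twice = rescale_unit_mean(once)
        assert np.array_equal(once.factors, twice.factors)

    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving_and_unit_mean(self, vals):
        from srtnorm.normalization import ScalingFactors
        sf = ScalingFactors([f"c{i}" for i in range(len(vals))],
                            np.array(vals), "library_size")
        out = rescale_unit_mean(sf)
        assert out.factors.mean() == pytest.approx(1.0, rel=1e-9)
        assert np.array_equal(np.argsort(out.factors), np.argsort(sf.factors))


class TestPearsonResiduals:
    def test_rank_one_counts_give_zero(self):
        # counts exactly equal to mu = outer product / grand total
        row = np.array([1.0, 2.0, 4.0])
        col = np.array([10.0, 20.0])
        v = np.outer(row, col) / (row.sum() * col.sum() / (row.sum() * col.sum()))
        v = np.outer(row / row.sum(), col)  # columns sum to col, rank 1
        cm = _cm(v * 7)
        out = pearson_residual_normalize(cm)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_no_negative_output(self):
        rng = np.random.default_rng(9)
        cm = _cm(rng.poisson(2.0, (30, 20)).astype(float))
        out = pearson_residual_normalize(cm)
        assert np.all(out.values >= 0)

    def test_poisson_limit(self):
        rng = np.random.default_rng(10)
        v = rng.poisson(5.0, (15, 10)).astype(float) + 1
        cm = _cm(v)
        mu = np.outer(v.sum(axis=1), v.sum(axis=0)) / v.sum()
        poisson = np.clip((v - mu) / np.sqrt(mu), 0.0, np.sqrt(10))
        out = pearson_residual_normalize(cm, theta=1e9)
        assert np.allclose(out.values, poisson, atol=1e-6)

    def test_clip_at_sqrt_n(self):
        v = np.ones((2, 9))
        v[0, 0] = 1e6
        out = pearson_residual_normalize(_cm(v))
        assert out.values.max() <= np.sqrt(9) + 1e-12

    def test_zero_grand_total_rejected(self):
        with pytest.raises(ValueError):
            pearson_residual_normalize(_cm(np.zeros((2, 2))))


class TestFilterZeroCells:
    def test_census(self):
        cm = _cm([[1, 0, 2], [0, 0, 1]])
        kept, census = filter_zero_cells(cm)
        assert kept.n_cells == 2
        assert census == {"n_cells_in": 3, "n_cells_kept": 2, "n_cells_dropped": 1}
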