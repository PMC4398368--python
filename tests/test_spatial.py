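"""Suitability extraction, spatial weights, Moran's I, layer PCA."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from faniche.morphio import SuitabilityRaster
from faniche.spatial import (
    EARTH_RADIUS_KM,
    extract_local_suitability,
    extract_regional_suitability,
    haversine_km,
    inverse_distance_weights,
    morans_i,
    pca_layer_selection,
)


def raster_2x2():
    return SuitabilityRaster(np.array([[0.1, 0.2], [0.3, 0.4]]), cell_size=1.0, origin=(0.0, 0.0))


class TestExtraction:
    def test_local_cell_geometry(self):
        assert extract_local_suitability(raster_2x2(), lat=0.5, lon=0.5) == pytest.approx(0.3)
        assert extract_local_suitability(raster_2x2(), lat=1.5, lon=1.5) == pytest.approx(0.2)

    def test_cell_edge_half_open_convention(self):
        # point on an interior vertical edge belongs to the eastern cell
        assert extract_local_suitability(raster_2x2(), lat=0.5, lon=1.0) == pytest.approx(0.4)

    def test_point_outside_extent(self):
        with pytest.raises(ValueError, match="outside raster extent"):
            extract_local_suitability(raster_2x2(), lat=5.0, lon=0.5)

    def test_local_matches_index_arithmetic_oracle(self, rng):
        for _ in range(100):
            nrows, ncols = rng.integers(2, 10, 2)
            cell = rng.uniform(0.1, 2.0)
            x0, y0 = rng.uniform(-50, 0, 2)
            values = rng.uniform(0, 1, (nrows, ncols))
            ras = SuitabilityRaster(values, cell_size=cell, origin=(x0, y0))
            lon = rng.uniform(x0, x0 + ncols * cell * 0.999)
            lat = rng.uniform(y0, y0 + nrows * cell * 0.999)
            col = int((lon - x0) // cell)
            row_south = int((lat - y0) // cell)
            expect = values[nrows - 1 - row_south, col]
            assert extract_local_suitability(ras, lat, lon) == pytest.approx(expect)

    def test_regional_constant_field(self):
        ras = SuitabilityRaster(np.full((3, 3), 0.5), cell_size=1.0, origin=(0, 0))
        for lat in (0.5, 1.5, 2.5):
            for lon in (0.5, 1.5, 2.5):
                assert extract_regional_suitability(ras, lat, lon) == pytest.approx(0.5)

    def test_regional_center_mean(self):
        values = np.arange(0.1, 1.0, 0.1).reshape(3, 3)
        ras = SuitabilityRaster(values, cell_size=1.0, origin=(0, 0))
        assert extract_regional_suitability(ras, lat=1.5, lon=1.5) == pytest.approx(0.5)

    def test_regional_matches_neighborhood_enumeration(self, rng):
        for _ in range(100):
            nrows, ncols = rng.integers(3, 8, 2)
            values = rng.uniform(0, 1, (nrows, ncols))
            values[rng.uniform(size=(nrows, ncols)) < 0.1] = -9999.0
            ras = SuitabilityRaster(values, cell_size=1.0, origin=(0, 0))
            row, col = rng.integers(0, nrows), rng.integers(0, ncols)
            lat = nrows - row - 0.5
            lon = col + 0.5
            neighborhood = [
                values[r, c]
                for r in range(max(0, row - 1), min(nrows, row + 2))
                for c in range(max(0, col - 1), min(ncols, col + 2))
                if values[r, c] != -9999.0
            ]
            got = extract_regional_suitability(ras, lat, lon)
            if neighborhood:
                assert got == pytest.approx(np.mean(neighborhood))
            else:
                assert np.isnan(got)

    def test_corner_focal_cell_truncation(self, rng):
        values = rng.uniform(0, 1, (5, 5))
        ras = SuitabilityRaster(values, cell_size=1.0, origin=(0, 0))
        # NW corner cell: only the 2x2 in-bounds block contributes
        got = extract_regional_suitability(ras, lat=4.5, lon=0.5)
        assert got == pytest.approx(values[:2, :2].mean())

    def test_exclude_focal_option(self):
        values = np.arange(0.1, 1.0, 0.1).reshape(3, 3)
        ras = SuitabilityRaster(values, cell_size=1.0, origin=(0, 0))
        got = extract_regional_suitability(ras, 1.5, 1.5, exclude_focal=True)
        assert got == pytest.approx((values.sum() - values[1, 1]) / 8)


class TestWeights:
    def test_equator_degree(self):
        d = haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(2 * np.pi * EARTH_RADIUS_KM / 360, rel=1e-12)
        loc = pd.DataFrame(
            {"population_id": list("abc"), "latitude": [0, 0, 0], "longitude": [0, 1, 3]}
        )
        w = inverse_distance_weights(loc)
        assert w[0, 1] == pytest.approx(1 / d, rel=1e-12)
        assert np.all(np.diag(w) == 0)

    def test_antipodal_distance(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(np.pi * EARTH_RADIUS_KM)

    def test_symmetry(self, rng):
        loc = pd.DataFrame(
            {
                "population_id": [f"p{i}" for i in range(8)],
                "latitude": rng.uniform(-30, 0, 8),
                "longitude": rng.uniform(-50, -35, 8),
            }
        )
        w = inverse_distance_weights(loc)
        assert np.allclose(w, w.T)

    def test_coincident_localities_named(self):
        loc = pd.DataFrame(
            {"population_id": list("abc"), "latitude": [0, 0, 5], "longitude": [0, 0, 5]}
        )
        with pytest.raises(ValueError, match="'a' and 'b'"):
            inverse_distance_weights(loc)

    def test_row_standardization(self, rng):
        loc = pd.DataFrame(
            {
                "population_id": [f"p{i}" for i in range(5)],
                "latitude": rng.uniform(-30, 0, 5),
                "longitude": rng.uniform(-50, -35, 5),
            }
        )
        w = inverse_distance_weights(loc, row_standardize=True)
        assert np.allclose(w.sum(axis=1), 1.0)


def rook_lattice(side):
    n = side * side
    w = np.zeros((n, n))
    for i in range(side):
        for j in range(side):
            a = i * side + j
            for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                ii, jj = i + di, j + dj
                if 0 <= ii < side and 0 <= jj < side:
                    w[a, ii * side + jj] = 1.0
    return w


class TestMoransI:
    def test_expected_value_for_22_samples(self, rng):
        values = rng.normal(size=22)
        w = rook_lattice(5)[:22, :22]
        np.fill_diagonal(w, 0)
        res = morans_i(values, w)
        assert res.expected == pytest.approx(-1 / 21, abs=1e-15)

    def test_gradient_on_lattice_matches_double_sum_oracle(self):
        side = 5
        lat = np.repeat(np.arange(side), side).astype(float)
        w = rook_lattice(side)
        res = morans_i(lat, w)
        z = lat - lat.mean()
        n = lat.size
        num = sum(
            w[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
        )
        oracle = (n / w.sum()) * num / (z**2).sum()
        assert res.observed == pytest.approx(oracle, abs=1e-12)
        assert res.observed > 0
        assert res.p_value < 0.01

    def test_invariances(self, rng):
        values = rng.normal(size=16)
        w = rook_lattice(4)
        base = morans_i(values, w).observed
        assert morans_i(values + 7.3, w).observed == pytest.approx(base, abs=1e-12)
        assert morans_i(values * 2.5, w).observed == pytest.approx(base, abs=1e-12)
        assert morans_i(values, w * 4.2).observed == pytest.approx(base, abs=1e-12)

    def test_null_rejection_rate(self):
        side = 5
        w = rook_lattice(side)
        rejections = 0
        n_sim = 500
        for seed in range(n_sim):
            values = np.random.default_rng(seed).normal(size=side * side)
            if morans_i(values, w).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_permutation_null_mean_is_expected(self, rng):
        values = rng.normal(size=16)
        w = rook_lattice(4)
        sims = []
        for _ in range(10000):
            perm = rng.permutation(values)
            z = perm - perm.mean()
            sims.append((16 / w.sum()) * (z @ w @ z) / (z @ z))
        assert np.mean(sims) == pytest.approx(-1 / 15, abs=3 * np.std(sims) / 100)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            morans_i(np.ones(9), rook_lattice(3))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_ape_reference(self, rng):
        n = 12
        loc = pd.DataFrame(
            {
                "population_id": [f"p{i}" for i in range(n)],
                "latitude": rng.uniform(-25, -5, n),
                "longitude": rng.uniform(-50, -35, n),
            }
        )
        w = inverse_distance_weights(loc)
        x = rng.normal(size=n) + 0.1 * loc["latitude"].to_numpy()
        # ape row-standardizes internally; match that convention explicitly
        res = morans_i(x, w / w.sum(axis=1, keepdims=True))
        script = (
            "library(ape)\n"
            f"w <- matrix(c({','.join(f'{v:.17g}' for v in w.ravel())}), nrow={n}, byrow=TRUE)\n"
            f"x <- c({','.join(f'{v:.17g}' for v in x)})\n"
            "r <- Moran.I(x, w)\n"
            'cat(sprintf("%.15g %.15g %.15g %.15g", r$observed, r$expected, r$sd, r$p.value))\n'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        obs, exp, sd, p = map(float, out.stdout.split())
        assert res.observed == pytest.approx(obs, abs=1e-10)
        assert res.expected == pytest.approx(exp, abs=1e-12)
        assert res.sd == pytest.approx(sd, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestLayerSelection:
    def test_duplicate_plus_independent_layer(self, rng):
        base = rng.normal(size=(20, 20))
        layers = {
            "a": base,
            "b": base * 2.0 + 1.0,  # perfectly correlated with a
            "c": rng.normal(size=(20, 20)),
        }
        sel = pca_layer_selection(layers, threshold=0.95)
        assert sel.axes_kept == 2
        assert len(sel.selected_layer_ids) == 2
        assert "c" in sel.selected_layer_ids

    def test_independent_layers_need_all_axes(self, rng):
        # five mutually independent layers: every axis is needed to reach
        # 95% of the correlation structure
        layers = {f"v{i}": rng.normal(size=(40, 50)) for i in range(5)}
        sel = pca_layer_selection(layers, threshold=0.95)
        assert sel.axes_kept == 5
        assert set(sel.selected_layer_ids) <= set(layers)
        assert len(sel.selected_layer_ids) == len(set(sel.selected_layer_ids))

    def test_duplicate_layer_never_selected_twice(self, rng):
        base = rng.normal(size=(15, 15))
        layers = {"a": base, "a2": base.copy(), "b": rng.normal(size=(15, 15))}
        sel = pca_layer_selection(layers, threshold=1.0)
        assert len(sel.selected_layer_ids) == len(set(sel.selected_layer_ids))

    def test_constant_layer_rejected(self, rng):
        layers = {"a": np.full((5, 5), 0.3), "b": rng.normal(size=(5, 5))}
        with pytest.raises(ValueError, match="constant"):
            pca_layer_selection(layers)

    def test_nodata_dropped_listwise(self, rng):
        a = SuitabilityRaster(rng.uniform(0, 1, (10, 10)), 1.0, (0, 0))
        b_vals = rng.uniform(0, 1, (10, 10))
        b_vals[0, :] = -9999.0
        b = SuitabilityRaster(b_vals, 1.0, (0, 0))
        sel = pca_layer_selection({"a": a, "b": b}, threshold=0.5)
        assert sel.axes_kept >= 1
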