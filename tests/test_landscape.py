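"""Euclidean, least-cost, and climate-dissimilarity predictor construction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from popcompare.genotype_core import PopulationSite
from popcompare.landscape import (
    CostRaster,
    HabitatRule,
    bray_curtis_matrix,
    build_cost_raster,
    euclidean_matrix,
    least_cost_matrix,
    read_ascii_grid,
    read_feature_layers,
    write_ascii_grid,
    write_feature_layers,
)


def site(id_, x, y, **climate):
    return PopulationSite(id_, x, y, "", climate)


def oracle_least_cost(grid: np.ndarray, resolution: float,
                      a: tuple[int, int], b: tuple[int, int]) -> float:
    """Independent shortest-path search (networkx Dijkstra) on the lattice."""
    import networkx as nx

    nrows, ncols = grid.shape
    G = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nrows and 0 <= c2 < ncols:
                    scale = math.sqrt(2) if dr and dc else 1.0
                    w = resolution * scale * (grid[r, c] + grid[r2, c2]) / 2
                    G.add_edge((r, c), (r2, c2), weight=w)
    return nx.dijkstra_path_length(G, a, b)


class TestEuclidean:
    def test_table_coordinates_distance(self):
        m = euclidean_matrix(
            [site("Namakia", 585313, 8242761), site("Marambitsy", 569852, 8242662)]
        )
        assert m["Namakia", "Marambitsy"] == pytest.approx(15461.3, abs=0.5)

    def test_identical_coordinates_and_symmetry(self):
        m = euclidean_matrix(
            [site("a", 5, 5), site("b", 5, 5), site("c", 8, 9)]
        )
        assert m["a", "b"] == 0.0
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)


class TestCostRaster:
    def test_coastline_buffer_columns(self):
        # coastline along the west edge, 10-km buffer, 1-km cells:
        # exactly the 10 nearest columns are suitable
        rule = HabitatRule(
            {"coast": [(0.0, 0.0), (0.0, 30_000.0)]}, buffer_km=10.0
        )
        raster = build_cost_raster(rule, (0, 0, 30_000, 30_000), 1000.0)
        assert raster.shape == (30, 30)
        assert (raster.grid[:, :10] == 1).all()
        assert (raster.grid[:, 10:] == 100.0).all()

    def test_saturating_buffer(self):
        rule = HabitatRule({"river": [(0.0, 0.0), (0.0, 50_000.0)]}, buffer_km=75.0)
        raster = build_cost_raster(rule, (0, 0, 50_000, 50_000), 5000.0)
        assert (raster.grid == 1).all()

    def test_penalty_applies_beyond_buffer(self):
        rule = HabitatRule(
            {"coast": [(0.0, 0.0), (0.0, 20_000.0)]}, buffer_km=10.0,
            outside_penalty=100.0,
        )
        raster = build_cost_raster(rule, (0, 0, 20_000, 20_000), 1000.0)
        r, c = raster.cell_of(11_500.0, 10_000.0)  # 11.5 km from the coast
        assert raster.grid[r, c] == 100.0

    def test_feature_point_order_invariance(self):
        pts = [(0.0, 0.0), (0.0, 10_000.0), (0.0, 25_000.0)]
        a = build_cost_raster(
            HabitatRule({"f": pts}, 5.0), (0, 0, 25_000, 25_000), 2500.0
        )
        b = build_cost_raster(
            HabitatRule({"f": pts[::-1]}, 5.0), (0, 0, 25_000, 25_000), 2500.0
        )
        assert np.array_equal(a.grid, b.grid)

    def test_resolution_coarser_than_buffer_rejected(self):
        rule = HabitatRule({"f": [(0.0, 0.0)]}, buffer_km=1.0)
        with pytest.raises(ValueError, match="unresolvable"):
            build_cost_raster(rule, (0, 0, 10_000, 10_000), 5000.0)


class TestLeastCost:
    def test_uniform_strip_is_grid_distance(self):
        raster = CostRaster((0, 0), 100.0, np.ones((1, 5)))
        m = least_cost_matrix(raster, [site("a", 50, 50), site("b", 450, 50)])
        assert m["a", "b"] == pytest.approx(400.0)

    def test_expensive_middle_cell(self):
        g = np.ones((1, 5))
        g[0, 2] = 10.0
        raster = CostRaster((0, 0), 100.0, g)
        m = least_cost_matrix(raster, [site("a", 50, 50), site("b", 450, 50)])
        # 100 * ((1+10)/2 + (10+1)/2 + 1 + 1) under the average-cost convention
        assert m["a", "b"] == pytest.approx(1300.0)

    def test_matches_exhaustive_search_on_small_grids(self):
        rng = np.random.default_rng(31)
        for trial in range(6):
            nrows, ncols = rng.integers(2, 7, 2)
            grid = 1.0 + rng.integers(0, 5, (nrows, ncols)).astype(float) * 2
            raster = CostRaster((0, 0), 50.0, grid)
            a_cell = (0, 0)
            b_cell = (int(nrows) - 1, int(ncols) - 1)
            sites = [
                site("a", 25.0, (nrows - 1 - a_cell[0]) * 50 + 25.0),
                site("b", b_cell[1] * 50 + 25.0, (nrows - 1 - b_cell[0]) * 50 + 25.0),
            ]
            got = least_cost_matrix(raster, sites)["a", "b"]
            want = oracle_least_cost(grid, 50.0, a_cell, b_cell)
            assert got == pytest.approx(want, abs=1e-9), (trial, grid)

    def test_uniform_raster_bounds_vs_euclidean(self):
        raster = CostRaster((0, 0), 100.0, np.ones((12, 12)))
        sites = [site("a", 150, 150), site("b", 950, 550)]
        lc = least_cost_matrix(raster, sites)["a", "b"]
        eu = euclidean_matrix(sites)["a", "b"]
        assert lc >= eu - 1e-9
        # 8-connectivity overshoot is at most ~8.2% plus one-cell slack
        assert lc <= eu * 1.0824 + raster.resolution

    def test_raising_costs_never_shortens_paths(self):
        rng = np.random.default_rng(8)
        grid = 1.0 + rng.random((6, 6)) * 3
        raster = CostRaster((0, 0), 10.0, grid)
        sites = [site("a", 5, 5), site("b", 55, 55)]
        base = least_cost_matrix(raster, sites)["a", "b"]
        for _ in range(5):
            g2 = grid.copy()
            r, c = rng.integers(0, 6, 2)
            g2[r, c] += rng.random() * 5
            higher = least_cost_matrix(CostRaster((0, 0), 10.0, g2), sites)["a", "b"]
            assert higher >= base - 1e-9

    def test_nodata_site_rejected_and_barrier_is_na(self):
        g = np.ones((3, 3))
        g[:, 1] = np.nan  # impassable column
        raster = CostRaster((0, 0), 10.0, g)
        with pytest.raises(ValueError, match="nodata cell"):
            least_cost_matrix(raster, [site("x", 15, 15), site("y", 25, 25)])
        with pytest.warns(UserWarning, match="no finite-cost path"):
            m = least_cost_matrix(raster, [site("a", 5, 15), site("b", 25, 15)])
        assert math.isnan(m["a", "b"])


class TestBrayCurtis:
    def test_examples(self):
        sites = [
            site("a", 0, 0, precip=400.0),
            site("b", 0, 0, precip=400.0),
            site("c", 0, 0, precip=300.0),
            site("d", 0, 0, precip=0.0),
        ]
        m = bray_curtis_matrix(sites, "precip")
        assert m["a", "b"] == 0.0
        assert m["a", "c"] == pytest.approx(100 / 700)
        assert m["a", "d"] == 1.0  # x vs 0 is maximal
        two = bray_curtis_matrix(
            [site("x", 0, 0, v=100.0), site("y", 0, 0, v=300.0)], "v"
        )
        assert two["x", "y"] == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        sites = [site(f"s{i}", 0, 0, v=float(rng.random() * 900)) for i in range(8)]
        m = bray_curtis_matrix(sites, "v")
        off = m.condensed()
        assert ((off >= 0) & (off <= 1)).all()

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bray_curtis_matrix(
                [site("a", 0, 0, v=-1.0), site("b", 0, 0, v=2.0)], "v"
            )


class TestGridIO:
    def test_ascii_round_trip(self, tmp_path):
        g = np.array([[1.0, 2.0, np.nan], [4.0, 1.0, 100.0]])
        raster = CostRaster((1000.0, 2000.0), 250.0, g)
        p = tmp_path / "r.asc"
        write_ascii_grid(raster, p)
        back = read_ascii_grid(p)
        assert back.origin == raster.origin
        assert back.resolution == raster.resolution
        assert np.array_equal(np.isnan(back.grid), np.isnan(g))
        assert np.allclose(back.grid[~np.isnan(g)], g[~np.isnan(g)])

    def test_header_validation(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 2\n1 2\n")
        with pytest.raises(ValueError, match="missing ESRI ASCII header"):
            read_ascii_grid(p)

    def test_feature_layer_round_trip(self, tmp_path):
        layers = {"coast": [(0.0, 1.0), (2.0, 3.0)], "river": [(9.0, 9.0)]}
        p = tmp_path / "f.csv"
        write_feature_layers(layers, p)
        assert read_feature_layers(p) == layers
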