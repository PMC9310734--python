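import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from landpop.geo import haversine_km
from landpop.raster import Raster
from landpop.resistance import (
    CostSurface,
    build_transition_graph,
    elevation_mask,
    least_cost_distances,
    suitability_cost_surface,
    terrain_ruggedness,
    tri_cost_surface,
)
from landpop.synthetic import LocalityTable


def locality_table(points):
    df = pd.DataFrame({
        "individual": [f"i{k}" for k in range(len(points))],
        "locality": [f"L{k}" for k in range(len(points))],
        "lon": [p[0] for p in points],
        "lat": [p[1] for p in points],
    })
    return LocalityTable.from_sample_sheet(df)


def nx_distances(graph, nodes):
    G = nx.Graph()
    G.add_nodes_from(range(graph.n_nodes))
    coo = graph.weights.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        G.add_edge(int(i), int(j), weight=min(w, G.get_edge_data(int(i), int(j), {"weight": np.inf})["weight"]) if G.has_edge(int(i), int(j)) else w)
    out = np.zeros((len(nodes), len(nodes)))
    for a, na in enumerate(nodes):
        for b, nb in enumerate(nodes):
            if a < b:
                try:
                    d = nx.shortest_path_length(G, na, nb, weight="weight")
                except nx.NetworkXNoPath:
                    d = np.inf
                out[a, b] = out[b, a] = d
    return out


class TestTRI:
    def test_flat_is_zero(self):
        tri = terrain_ruggedness(Raster(np.full((5, 5), 7.0), 0, 0.5, 0.1))
        assert np.nanmax(tri.values) == 0

    def test_hand_sum(self):
        v = np.full((3, 3), 10.0)
        v[0, 0] = 13.0
        tri = terrain_ruggedness(Raster(v, 0, 0.3, 0.1))
        assert tri.values[1, 1] == pytest.approx(3.0)

    def test_translation_invariance(self, rng):
        v = rng.uniform(0, 100, (6, 6))
        a = terrain_ruggedness(Raster(v, 0, 0.6, 0.1))
        b = terrain_ruggedness(Raster(v + 500, 0, 0.6, 0.1))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError, match="nodata"):
            terrain_ruggedness(Raster(np.full((3, 3), np.nan), 0, 0.3, 0.1))


class TestElevationMask:
    def test_elevation_band_rule(self, rng):
        elev = Raster(rng.uniform(0, 3000, (20, 20)), 0, 2.0, 0.1)
        elev.values[0, 0] = 350.0
        elev.values[0, 1] = 450.0
        occ = np.array([[0.5, 1.5], [1.5, 0.5], [1.0, 1.0], [0.05, 1.95], [1.95, 0.05]])
        occ_elev = np.array([500.0, 1200, 2000, 800, 1500])
        masked = elevation_mask(elev, occ, occ_elev, hull_buffer_deg=2.0)
        assert masked.nodata_mask[0, 0]        # 350 < 500 - 100
        assert not masked.nodata_mask[0, 1]    # 450 >= 400
        high = elev.values > 2100
        assert masked.nodata_mask[high].all()

    def test_outside_hull_masked_regardless_of_elevation(self):
        elev = Raster(np.full((20, 20), 1000.0), 0, 2.0, 0.1)
        occ = np.array([[0.2, 1.8], [0.4, 1.8], [0.3, 1.6]])
        masked = elevation_mask(elev, occ, np.array([900.0, 1000, 1100]),
                                hull_buffer_deg=0.1)
        assert masked.nodata_mask[19, 19]      # far corner, right elevation band

    def test_lower_bound_zero_keeps_low_cells(self):
        elev = Raster(np.full((10, 10), 100.0), 0, 1.0, 0.1)
        occ = np.array([[0.2, 0.8], [0.8, 0.2], [0.5, 0.5]])
        occ_elev = np.array([1000.0, 1500, 2000])
        with pytest.raises(ValueError, match="no passable"):
            elevation_mask(elev, occ, occ_elev, hull_buffer_deg=1.0)
        masked = elevation_mask(elev, occ, occ_elev, hull_buffer_deg=1.0,
                                lower_bound_zero=True)
        assert not masked.nodata_mask.all()


class TestTierScheme:
    occ = np.arange(1.0, 101.0)

    @pytest.mark.parametrize("value,cost", [
        (50.0, 1), (150.0, 16), (97.0, 8), (0.5, 16), (12.5, 2), (7.0, 4),
        (3.0, 8), (88.0, 2), (93.0, 4), (15.85, 1), (85.05, 1),
    ])
    def test_tier_assignment(self, value, cost):
        tri = Raster(np.array([[value]]), 0, 0.01, 0.01)
        cs = tri_cost_surface(tri, self.occ)
        assert cs.raster.values[0, 0] == cost

    def test_brute_force_ranking_oracle(self):
        probes = np.linspace(-10, 110, 1000)
        tri = Raster(probes[None, :], 0, 0.01, 0.01)
        cs = tri_cost_surface(tri, self.occ)
        q = np.quantile(self.occ, [0, 0.05, 0.10, 0.15, 0.85, 0.90, 0.95, 1.0])
        for v, c in zip(probes, cs.raster.values[0]):
            if v < q[0] or v > q[7]:
                expected = 16
            elif q[3] <= v <= q[4]:
                expected = 1
            elif q[2] <= v <= q[5]:
                expected = 2
            elif q[1] <= v <= q[6]:
                expected = 4
            else:
                expected = 8
            assert c == expected, f"probe {v}"

    def test_only_tier_values_present(self, rng):
        tri = Raster(rng.uniform(-20, 140, (10, 10)), 0, 1.0, 0.1)
        cs = tri_cost_surface(tri, self.occ)
        assert set(np.unique(cs.raster.values)) <= {1, 2, 4, 8, 16}

    def test_occurrence_tier_frequencies(self):
        occ = np.linspace(0, 1, 1001)
        tri = Raster(occ[None, :], 0, 0.01, 0.01)
        cs = tri_cost_surface(tri, occ)
        vals = cs.raster.values[0]
        assert abs((vals == 1).mean() - 0.70) < 0.02
        assert abs((vals == 2).mean() - 0.10) < 0.02
        assert abs((vals == 4).mean() - 0.10) < 0.02
        assert abs((vals == 8).mean() - 0.10) < 0.02

    def test_constant_reference_degenerate_rule(self):
        tri = Raster(np.array([[5.0, 7.0]]), 0, 0.01, 0.01)
        with pytest.warns(UserWarning, match="constant"):
            cs = tri_cost_surface(tri, np.full(25, 5.0))
        assert cs.raster.values[0, 0] == 1 and cs.raster.values[0, 1] == 16


class TestSuitabilityCost:
    def test_boundary_values_and_involution(self, rng):
        suit = Raster(rng.uniform(0, 1, (4, 4)), 0, 0.4, 0.1)
        suit.values[0, 0], suit.values[0, 1] = 1.0, 0.0
        cost = suitability_cost_surface(suit)
        assert cost.raster.values[0, 0] == 0.0
        assert cost.raster.values[0, 1] == 1.0
        back = suitability_cost_surface(cost.raster)
        np.testing.assert_allclose(back.raster.values, suit.values, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            suitability_cost_surface(Raster(np.array([[1.5]]), 0, 0.01, 0.01))


class TestTransitionGraph:
    def test_degrees(self):
        g = build_transition_graph(CostSurface(Raster(np.ones((8, 8)), 0, 0.8, 0.1),
                                               "terrain-tier"))
        assert g.degree(4, 4) == 16
        assert g.degree(0, 0) == 5

    def test_cost_linearity(self, rng):
        vals = rng.uniform(0.5, 3, (5, 5))
        g1 = build_transition_graph(CostSurface(Raster(vals, 0, 0.5, 0.1), "terrain-tier"))
        g2 = build_transition_graph(CostSurface(Raster(2 * vals, 0, 0.5, 0.1), "terrain-tier"))
        np.testing.assert_allclose(g2.weights.toarray(), 2 * g1.weights.toarray(), rtol=1e-12)

    def test_no_edges_into_masked_cells(self):
        vals = np.ones((4, 4))
        vals[1, 1] = np.nan
        g = build_transition_graph(CostSurface(Raster(vals, 0, 0.4, 0.1), "terrain-tier"))
        assert g.n_nodes == 15
        assert (g.node_rows != 1).any() or (g.node_cols != 1).any()


class TestLeastCost:
    def test_uniform_strip_closed_form(self):
        strip = CostSurface(Raster(np.ones((1, 3)), 0.0, 0.005, 0.01), "terrain-tier")
        g = build_transition_graph(strip)
        loc = locality_table([(0.005, 0.0), (0.025, 0.0)])
        d = least_cost_distances(g, loc)
        assert d.values[0, 1] == pytest.approx(2 * haversine_km(0, 0, 0.01, 0), rel=1e-9)

    def test_self_distance_zero(self):
        g = build_transition_graph(CostSurface(Raster(np.ones((4, 4)), 0, 0.4, 0.1),
                                               "terrain-tier"))
        loc = locality_table([(0.05, 0.35), (0.35, 0.05), (0.2, 0.2)])
        d = least_cost_distances(g, loc)
        np.testing.assert_allclose(np.diag(d.values), 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.5, 4, (6, 6))
        if seed % 2:
            vals[3, :5] = np.nan   # barrier with one gap
        cost = CostSurface(Raster(vals, 0, 0.06, 0.01), "terrain-tier")
        g = build_transition_graph(cost)
        pts = [(0.005, 0.055), (0.055, 0.005), (0.035, 0.035)]
        loc = locality_table(pts)
        d = least_cost_distances(g, loc)
        idx = g.node_index()
        nodes = [idx[g.raster.index_of(lon, lat)] for lon, lat in pts]
        expected = nx_distances(g, nodes)
        np.testing.assert_allclose(d.values, expected, rtol=1e-9)

    def test_barrier_insertion_never_decreases_distance(self, rng):
        vals = rng.uniform(0.5, 4, (6, 6))
        base = CostSurface(Raster(vals.copy(), 0, 0.06, 0.01), "terrain-tier")
        pts = [(0.005, 0.055), (0.055, 0.005)]
        loc = locality_table(pts)
        d0 = least_cost_distances(build_transition_graph(base), loc).values[0, 1]
        for r, c in [(2, 2), (3, 3), (2, 3)]:
            vals2 = vals.copy()
            vals2[r, c] = np.nan
            masked = CostSurface(Raster(vals2, 0, 0.06, 0.01), "terrain-tier")
            d1 = least_cost_distances(build_transition_graph(masked), loc).values[0, 1]
            assert d1 >= d0 - 1e-12

    def test_lower_bound_great_circle_times_min_cost(self, rng):
        vals = rng.uniform(1.0, 5, (6, 6))
        cost = CostSurface(Raster(vals, 0, 0.06, 0.01), "terrain-tier")
        g = build_transition_graph(cost)
        pts = [(0.005, 0.055), (0.055, 0.005)]
        loc = locality_table(pts)
        d = least_cost_distances(g, loc).values[0, 1]
        gc = haversine_km(pts[0][0], pts[0][1], pts[1][0], pts[1][1])
        assert d >= gc * vals.min() * 0.999

    def test_unsnappable_locality_named_in_error(self):
        vals = np.ones((4, 4))
        cost = CostSurface(Raster(vals, 0, 0.4, 0.1), "terrain-tier")
        g = build_transition_graph(cost)
        loc = locality_table([(0.05, 0.35), (5.0, 5.0), (0.2, 0.2)])
        with pytest.raises(ValueError, match="L1"):
            least_cost_distances(g, loc)
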