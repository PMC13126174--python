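"""Network reconstruction, connectivity scoring and null calibration."""

import itertools

import numpy as np
import pytest
from scipy.spatial import Delaunay

import classinet as cn
from classinet import connectivity as co

EQUILATERAL = np.array([[0.0, 0.0], [190.0, 0.0], [95.0, 95.0 * np.sqrt(3.0)]])


# ------------------------------------------------------- brute-force oracle


def oracle_range_links(points, lo, hi):
    """All unordered pairs with lo <= distance <= hi (exhaustive)."""
    out = set()
    for i, j in itertools.combinations(range(len(points)), 2):
        if lo <= np.linalg.norm(points[i] - points[j]) <= hi:
            out.add((i, j))
    return out


def oracle_delaunay(points, lo, hi):
    """Textual rule applied directly to the Delaunay edges/triangles."""
    tri = Delaunay(points)
    simplices = [tuple(sorted(s)) for s in tri.simplices]
    edges = set()
    for s in simplices:
        edges.update(itertools.combinations(s, 2))

    def in_range(e):
        return lo <= np.linalg.norm(points[e[0]] - points[e[1]]) <= hi

    kept = {e for e in edges if in_range(e)}
    for s in simplices:
        tri_edges = list(itertools.combinations(s, 2))
        ok = [in_range(e) for e in tri_edges]
        if sum(ok) == 2:
            kept.add(tri_edges[ok.index(False)])
    triangles = {
        s for s in simplices
        if all(e in kept for e in itertools.combinations(s, 2))
    }
    return kept, triangles


def oracle_three_cycles(n, links):
    out = set()
    for a, b, c in itertools.combinations(range(n), 3):
        if {(min(a, b), max(a, b)), (min(a, c), max(a, c)),
                (min(b, c), max(b, c))} <= links:
            out.add((a, b, c))
    return out


class TestReconstructionOracle:
    @pytest.mark.parametrize("seed", range(12))
    def test_delaunay_matches_rule_application(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        pts = rng.uniform(0, 600, (n, 2))
        net = co.reconstruct_network(pts, "delaunay", (160.0, 220.0))
        kept, tris = oracle_delaunay(pts, 160.0, 220.0)
        assert set(map(tuple, net.links)) == kept
        assert set(map(tuple, net.triangles)) == tris

    @pytest.mark.parametrize("seed", range(12))
    def test_range_links_and_crossing_resolution(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(4, 13)
        pts = rng.uniform(0, 600, (n, 2))
        net = co.reconstruct_network(pts, "range", (160.0, 220.0), seed=seed)
        all_pairs = oracle_range_links(pts, 160.0, 220.0)
        got = set(map(tuple, net.links))
        assert got <= all_pairs
        # planarity: no surviving pair crosses
        assert len(co._crossing_pairs(pts, net.links)) == 0
        # every removed link must have crossed a surviving one
        removed = all_pairs - got
        full = np.asarray(sorted(all_pairs), dtype=int).reshape(-1, 2)
        crossing = co._crossing_pairs(pts, full)
        crossing_links = {tuple(full[i]) for pair in crossing for i in pair}
        assert removed <= crossing_links
        # triangles are exactly the 3-cycles of the surviving graph
        assert set(map(tuple, net.triangles)) == oracle_three_cycles(n, got)

    def test_equilateral_triangle_both_methods(self):
        for method in ("range", "delaunay"):
            net = co.reconstruct_network(EQUILATERAL, method, (160.0, 220.0))
            assert net.n_links == 3
            assert len(net.triangles) == 1

    def test_below_range_pair_unlinked(self):
        net = co.reconstruct_network(
            np.array([[0.0, 0.0], [150.0, 0.0]]), "range", (160.0, 220.0)
        )
        assert net.n_links == 0

    def test_sole_out_of_range_edge_preserved(self):
        """Triangle with sides 190/200/240: the 240 edge is the only
        out-of-range edge, so the preservation rule retains all three."""
        # place: A=(0,0), B=(190,0); C with |AC|=200, |BC|=240
        x = (190.0**2 + 200.0**2 - 240.0**2) / (2 * 190.0)
        y = np.sqrt(200.0**2 - x**2)
        pts = np.array([[0.0, 0.0], [190.0, 0.0], [x, y]])
        net = co.reconstruct_network(pts, "delaunay", (160.0, 220.0))
        assert net.n_links == 3
        assert len(net.triangles) == 1

    def test_fewer_than_three_nodes_falls_back_to_range(self):
        net = co.reconstruct_network(
            np.array([[0.0, 0.0], [190.0, 0.0]]), "delaunay", (160.0, 220.0)
        )
        assert net.n_links == 1
        assert len(net.triangles) == 0


class TestConnectivityScores:
    WINDOW = (0.0, 0.0, 1024.0, 1024.0)

    def test_empty_graph_scores_zero(self):
        net = co.reconstruct_network(np.zeros((0, 2)), "delaunay")
        s = co.connectivity_scores(net, self.WINDOW)
        assert (s.link_count, s.triangle_count, s.triangle_area_sum) == (0, 0, 0)

    def test_equilateral_triangle_closed_form(self):
        net = co.reconstruct_network(EQUILATERAL + 300.0, "delaunay", (160.0, 220.0))
        s = co.connectivity_scores(net, self.WINDOW)
        assert s.link_count == 3
        assert s.triangle_count == 1
        assert s.triangle_area_sum == pytest.approx(np.sqrt(3.0) / 4.0 * 190.0**2)

    def test_rhombus_enumeration(self):
        """Two triangles sharing an edge: 5 links, 2 triangles."""
        pts = np.vstack([EQUILATERAL, [[285.0, 95.0 * np.sqrt(3.0)]]]) + 300.0
        net = co.reconstruct_network(pts, "delaunay", (160.0, 220.0))
        s = co.connectivity_scores(net, self.WINDOW)
        assert s.link_count == 5
        assert s.triangle_count == 2

    def test_centroid_outside_window_not_counted(self):
        net = co.reconstruct_network(EQUILATERAL + 1000.0, "delaunay", (160.0, 220.0))
        s = co.connectivity_scores(net, self.WINDOW)
        assert s.triangle_count == 0


class TestHeatmapAndNull:
    def test_empty_field_gives_zero_heatmap(self):
        mask = cn.full_mask((2048.0, 2048.0))
        maps = co.connectivity_heatmap(np.zeros((0, 2)), mask)
        assert np.nanmax(maps.pixel_maps["triangle_area_sum"]) == 0.0

    def test_zero_density_null_is_zero(self):
        null = co.null_threshold(0.0, seed=1)
        assert all(v == 0.0 for v in null.thresholds.values())

    def test_null_determinism(self):
        a = co.null_threshold(30.0, n_reps=30, seed=5)
        b = co.null_threshold(30.0, n_reps=30, seed=5)
        assert a.thresholds == b.thresholds

    def test_csr_heatmap_stationary(self):
        """No spatial trend on a homogeneous random field: left and right
        half means agree within a few window-score standard errors."""
        ext = (6144.0, 6144.0)
        clusters, _ = cn.simulate_pattern(
            cn.SimConfig(pattern="csr", density=40.0, extent=ext, seed=9)
        )
        maps = co.connectivity_heatmap(clusters, cn.full_mask(ext))
        ws = maps.window_scores["triangle_area_sum"]
        cols = maps.window_origins[:, 1]
        left, right = ws[cols < 11], ws[cols >= 11]
        se = ws.std() * np.sqrt(1 / len(left) + 1 / len(right))
        assert abs(left.mean() - right.mean()) < 4 * se

    def test_island_scores_above_background(self, oned_composite):
        clusters, truth, ext = oned_composite
        maps = co.connectivity_heatmap(clusters, cn.full_mask(ext))
        tas = maps.pixel_maps["triangle_area_sum"]
        assert np.nanmean(tas[truth.island_mask]) > np.nanmean(tas[~truth.island_mask])

    def test_segment_network_extremes(self):
        null = co.NullModel(1.0, {m: 10.0 for m in co.METRICS})
        low = np.full((8, 8), 5.0)
        high = np.full((8, 8), 20.0)
        assert not co.segment_network(low, null).any()
        assert co.segment_network(high, null).all()
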