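"""2D regularity features, similarity mapping and LDA integration."""

import numpy as np
import pytest

import classinet as cn
from classinet import regular2d as r2
from classinet.regular2d import DegenerateTrainingError, NodeFeatures


class TestNodeFeatures:
    def test_hex_interior_node_geometry(self, hex_truth):
        """Interior honeycomb node: 3 neighbors at 190 nm, 120 deg apart."""
        _, _, truth = hex_truth
        net = truth.true_network
        feats = r2.node_features(net)
        interior = [f for f in feats if f.neighbor_count == 3]
        assert interior
        f = interior[0]
        np.testing.assert_allclose(f.link_lengths, 190.0, atol=1e-6)
        gaps = np.diff(np.sort(f.link_angles))
        np.testing.assert_allclose(gaps, 120.0, atol=1e-6)

    def test_isolated_node(self):
        net = cn.NetworkGraph(
            np.array([[0.0, 0.0], [1000.0, 0.0]]), np.zeros((0, 2), int),
            np.zeros((0, 3), int),
        )
        feats = r2.node_features(net)
        assert feats[0].neighbor_count == 0
        assert feats[0].link_lengths.size == 0

    def test_collinear_neighbors(self):
        net = cn.NetworkGraph(
            np.array([[0.0, 0.0], [190.0, 0.0], [-190.0, 0.0]]),
            np.array([[0, 1], [0, 2]]), np.zeros((0, 3), int),
        )
        f = r2.node_features(net)[0]
        np.testing.assert_allclose(sorted(f.link_lengths), [190.0, 190.0])
        gap = abs(f.link_angles[0] - f.link_angles[1])
        assert min(gap, 360 - gap) == pytest.approx(180.0)


class TestSimilarityScores:
    def _feat(self, count, lengths, angles):
        return NodeFeatures(count, np.asarray(lengths, float), np.asarray(angles, float))

    def test_identical_nodes_score_one(self):
        f = self._feat(3, [190, 190, 190], [0, 120, 240])
        s = r2.similarity_scores(f, [f, f, f])
        assert (s.s_count, s.s_length, s.s_angle) == (1.0, 1.0, 1.0)

    def test_count_deviation_maps_to_quarter(self):
        """count 3 vs neighbors all count 6 -> dev 3 -> s_count = 1/4."""
        node = self._feat(3, [190] * 3, [0, 120, 240])
        nb = self._feat(6, [190] * 6, [0, 60, 120, 180, 240, 300])
        s = r2.similarity_scores(node, [nb, nb, nb])
        assert s.s_count == pytest.approx(0.25)

    def test_no_neighbors_excluded(self):
        assert r2.similarity_scores(self._feat(0, [], []), []) is None

    def test_scores_strictly_decrease_with_deviation(self):
        node = self._feat(3, [190] * 3, [0, 120, 240])
        near = self._feat(3, [200] * 3, [0, 120, 240])
        far = self._feat(3, [240] * 3, [0, 120, 240])
        s_near = r2.similarity_scores(node, [near]).s_length
        s_far = r2.similarity_scores(node, [far]).s_length
        assert 1.0 > s_near > s_far > 0.0

    def test_angle_similarity_rotation_invariant(self):
        node = self._feat(3, [190] * 3, [0, 120, 240])
        rotated = self._feat(3, [190] * 3, [50, 170, 290])
        assert r2.similarity_scores(node, [rotated]).s_angle == pytest.approx(1.0)

    def test_lattice_beats_random_graph_on_angle_similarity(self, hex_truth):
        _, clusters, _ = hex_truth
        net_hex = cn.reconstruct_network(clusters, "delaunay", (160.0, 220.0))
        f_hex, v_hex = r2.regularity_features(net_hex)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 4000, (len(clusters), 2))
        net_csr = cn.reconstruct_network(pts, "delaunay", (160.0, 220.0))
        f_csr, v_csr = r2.regularity_features(net_csr)
        assert f_hex[v_hex, 2].mean() > f_csr[v_csr, 2].mean()


class TestTrainLDA:
    def _sets(self, jitter, seeds):
        return [
            cn.simulate_pattern(
                cn.SimConfig(pattern="2d_hex", extent=(3000.0, 3000.0),
                             jitter_sigma=jitter, seed=s)
            )[0]
            for s in seeds
        ]

    def test_well_separated_classes_classify_above_90pct(self):
        w = r2.train_lda(
            self._sets(0.0, range(3)), self._sets(60.0, range(10, 13)), seed=1
        )
        assert w.training_meta["holdout_accuracy"] > 0.9

    def test_identical_classes_degenerate(self):
        same = self._sets(10.0, range(3))
        with pytest.raises(DegenerateTrainingError):
            r2.train_lda(same, same, seed=1)

    def test_determinism(self):
        a = r2.train_lda(self._sets(0.0, [1]), self._sets(60.0, [2]), seed=3)
        b = r2.train_lda(self._sets(0.0, [1]), self._sets(60.0, [2]), seed=3)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_weights_json_roundtrip(self, tmp_path):
        w = r2.train_lda(self._sets(0.0, [1]), self._sets(60.0, [2]), seed=3)
        p = tmp_path / "weights.json"
        w.to_json(p)
        w2 = r2.LDAWeights.from_json(p)
        np.testing.assert_allclose(w.coefficients, w2.coefficients)
        assert w.intercept == pytest.approx(w2.intercept)


class TestHeatmapSegmentation:
    def test_ordered_lattice_segments_disordered_does_not(self):
        ext = (4096.0, 4096.0)
        mask = cn.full_mask(ext)
        w = r2.default_lda_weights(0)
        hex_c, _ = cn.simulate_pattern(cn.SimConfig(pattern="2d_hex", seed=11, extent=ext))
        from classinet.connectivity import measured_density

        dens = measured_density(hex_c.centroids, mask)
        thr = r2.regularity2d_null_threshold(dens, weights=w, seed=3, n_reps=60)
        dis_c, _ = cn.simulate_pattern(
            cn.SimConfig(pattern="2d_hex", jitter_sigma=60.0, miss_rate=0.2,
                         seed=12, extent=ext)
        )
        for clusters, expect_high in ((hex_c, True), (dis_c, False)):
            net = cn.reconstruct_network(clusters, "delaunay", (160.0, 220.0))
            hm = r2.regularity2d_heatmap(net, mask, weights=w)
            frac = r2.segment_2d(hm, thr).mean()
            if expect_high:
                assert frac > 0.8
            else:
                assert frac < 0.1

    def test_empty_window_missing(self):
        mask = cn.full_mask((2048.0, 2048.0))
        net = cn.reconstruct_network(np.zeros((0, 2)), "delaunay")
        hm = r2.regularity2d_heatmap(net, mask, weights=r2.default_lda_weights(0))
        assert np.isnan(hm).all()
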