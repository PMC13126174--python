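"""Synthetic SMLM generator: lattices, perturbations, composites."""

import numpy as np
import pytest

import classinet as cn
from classinet.simgen import SimConfig


class TestSimulatePattern:
    def test_hex_lattice_first_nnd_is_side_length(self, hex_truth):
        _, clusters, _ = hex_truth
        d1 = cn.knn_nnd(clusters, 1)[:, 0]
        np.testing.assert_allclose(d1, 190.0, atol=1e-6)

    def test_hex_interior_degree_three(self, hex_truth):
        _, _, truth = hex_truth
        net = truth.true_network
        deg = np.bincount(net.links.ravel(), minlength=net.n_nodes)
        assert (deg <= 3).all()
        assert (deg == 3).mean() > 0.5   # interior dominates at this extent

    def test_full_miss_rate_empties_clusters_but_not_truth(self):
        cfg = SimConfig(pattern="1d_periodic", miss_rate=1.0, seed=1)
        clusters, truth = cn.simulate_pattern(cfg)
        assert len(clusters) == 0
        assert len(truth.true_centroids) > 0

    def test_csr_poisson_mean(self):
        """Cluster count over seeds matches lambda*A within 3 standard errors."""
        density, ext = 20.0, (4000.0, 4000.0)
        counts = [
            len(cn.simulate_pattern(SimConfig(pattern="csr", density=density,
                                              miss_rate=0.0, extent=ext, seed=s))[0])
            for s in range(40)
        ]
        lam = density * 16.0
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_seed_reproducibility(self):
        cfg = SimConfig(pattern="1d_periodic", miss_rate=0.3, fp_rate=2.0, seed=7)
        a, _ = cn.simulate_pattern(cfg)
        b, _ = cn.simulate_pattern(cfg)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(pattern="spiral")

    def test_1d_line_spacing_in_truth(self):
        cfg = SimConfig(pattern="1d_periodic", jitter_sigma=0.0, rotation_deg=0.0,
                        seed=3, extent=(3000.0, 3000.0))
        _, truth = cn.simulate_pattern(cfg)
        ys = np.unique(np.round(truth.true_centroids[:, 1], 6))
        np.testing.assert_allclose(np.diff(ys), 190.0, atol=1e-6)


class TestEmitLocalizations:
    def test_degenerate_count_distribution(self):
        cfg = SimConfig(pattern="csr", density=5.0, seed=1,
                        locs_per_cluster=(np.log(20.0), 0.0))
        clusters, _ = cn.simulate_pattern(cfg)
        locs = cn.emit_localizations(clusters, cfg)
        assert len(locs) == 20 * len(clusters)

    def test_cluster_mean_near_centroid(self):
        """CLT bound: per-cluster localization mean within 3*sigma/sqrt(n)."""
        cfg = SimConfig(pattern="csr", density=10.0, seed=2, extent=(4000.0, 4000.0),
                        locs_per_cluster=(np.log(40.0), 0.0),
                        precision=(np.log(12.0), 0.0))
        clusters, _ = cn.simulate_pattern(cfg)
        assert len(clusters) >= 50
        locs = cn.emit_localizations(clusters, cfg)
        xy = locs.xy.reshape(len(clusters), 40, 2)
        err = np.linalg.norm(xy.mean(axis=1) - clusters.centroids, axis=1)
        bound = 3.0 * 12.0 / np.sqrt(40)
        assert (err < bound).mean() > 0.95

    def test_determinism(self):
        cfg = SimConfig(pattern="csr", density=5.0, seed=4)
        clusters, _ = cn.simulate_pattern(cfg)
        a = cn.emit_localizations(clusters, cfg)
        b = cn.emit_localizations(clusters, cfg)
        np.testing.assert_array_equal(a.x, b.x)

    def test_empty_clusters(self):
        cfg = SimConfig(pattern="csr", density=1.0, seed=1)
        assert len(cn.emit_localizations(cn.ClusterSet(np.zeros((0, 2))), cfg)) == 0


class TestMidpoints:
    def test_triangle_midpoints(self):
        nodes = np.array([[0.0, 0.0], [190.0, 0.0], [95.0, 164.5]])
        net = cn.NetworkGraph(nodes, [[0, 1], [0, 2], [1, 2]], np.zeros((0, 3), int))
        mids = cn.network_to_midpoints(net)
        assert len(mids) == 3
        np.testing.assert_allclose(sorted(mids.centroids[:, 0]), [47.5, 95.0, 142.5])

    def test_single_link_midpoint(self):
        net = cn.NetworkGraph([[0.0, 0.0], [190.0, 0.0]], [[0, 1]], np.zeros((0, 3), int))
        np.testing.assert_allclose(cn.network_to_midpoints(net).centroids, [[95.0, 0.0]])

    def test_link_count_conserved(self, hex_truth):
        _, _, truth = hex_truth
        net = truth.true_network
        assert len(cn.network_to_midpoints(net)) == net.n_links


class TestComposite:
    def test_label_grid_equals_island_mask(self, oned_composite):
        _, truth, _ = oned_composite
        np.testing.assert_array_equal(truth.label_grid == cn.LABEL_1D, truth.island_mask)

    def test_island_fraction_in_bounds(self):
        ext = (4096.0, 4096.0)
        for bseed in range(8):
            _, truth = cn.make_composite(
                SimConfig(pattern="1d_periodic", extent=ext, seed=1),
                SimConfig(pattern="csr", extent=ext, seed=2),
                boundary_seed=bseed,
            )
            assert 0.2 <= truth.island_mask.mean() <= 0.6

    def test_density_matched_across_boundary(self, oned_composite):
        """Island and background cluster densities agree within 10%."""
        clusters, truth, ext = oned_composite
        mask = truth.island_mask
        pitch = cn.GRID_PITCH
        ri = (clusters.centroids[:, 1] / pitch).astype(int).clip(0, mask.shape[0] - 1)
        ci = (clusters.centroids[:, 0] / pitch).astype(int).clip(0, mask.shape[1] - 1)
        inside = mask[ri, ci]
        area_in = mask.sum() * (pitch / 1000.0) ** 2
        area_out = (~mask).sum() * (pitch / 1000.0) ** 2
        d_in = inside.sum() / area_in
        d_out = (~inside).sum() / area_out
        assert abs(d_in - d_out) / d_in < 0.10

    def test_mismatched_extents_rejected(self):
        with pytest.raises(ValueError):
            cn.make_composite(
                SimConfig(pattern="csr", density=5.0, extent=(1000.0, 1000.0)),
                SimConfig(pattern="csr", density=5.0, extent=(2000.0, 2000.0)),
            )
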