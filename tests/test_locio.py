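"""I/O, rendering, cluster detection and cellular-area determination."""

import numpy as np
import pytest

import classinet as cn
from classinet.locio import FormatError, cellular_area, detect_clusters, read_localizations


def _write(tmp_path, text, name="locs.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadLocalizations:
    def test_identity_read(self, tmp_path):
        p = _write(tmp_path, "x_nm,y_nm\n10,20\n30,40\n50,60\n")
        t = read_localizations(p)
        assert len(t) == 3
        assert t.n_dropped == 0
        np.testing.assert_allclose(t.x, [10, 30, 50])

    def test_nonfinite_rows_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "x_nm,y_nm\n10,20\nnan,40\n50,60\n")
        t = read_localizations(p)
        assert len(t) == 2
        assert t.n_dropped == 1

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "x_nm,z\n10,20\n")
        with pytest.raises(FormatError):
            read_localizations(p)

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = _write(tmp_path, "")
        assert len(read_localizations(p)) == 0

    def test_custom_dialect(self, tmp_path):
        p = _write(tmp_path, "posx,posy\n1,2\n")
        t = read_localizations(p, dialect={"x": "posx", "y": "posy"})
        assert t.x[0] == 1.0 and t.y[0] == 2.0


class TestRenderImage:
    def test_single_localization_binning(self):
        t = cn.LocalizationTable(x=np.array([24.0]), y=np.array([40.0]))
        img = cn.render_image(t, 16.0, extent=(64.0, 64.0))
        assert img.pixels[2, 1] == 1.0
        assert img.pixels.sum() == 1.0

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        t = cn.LocalizationTable(x=rng.uniform(0, 999, 1000), y=rng.uniform(0, 999, 1000))
        img = cn.render_image(t, 16.0, extent=(1000.0, 1000.0))
        assert img.pixels.sum() == 1000

    def test_empty_table_renders_zero_image(self):
        img = cn.render_image(cn.LocalizationTable(np.zeros(0), np.zeros(0)),
                              16.0, extent=(320.0, 320.0))
        assert img.pixels.shape == (20, 20)
        assert img.pixels.sum() == 0

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            cn.render_image(cn.LocalizationTable(np.zeros(0), np.zeros(0)), 0.0)


class TestDetectClusters:
    def _field(self, centers, n_locs, sigma, seed, extent):
        rng = np.random.default_rng(seed)
        xy = np.vstack([c + rng.normal(0, sigma, (n_locs, 2)) for c in centers])
        locs = cn.LocalizationTable(x=xy[:, 0].clip(0), y=xy[:, 1].clip(0))
        img = cn.render_image(locs, 16.0, extent)
        return img, locs

    def test_single_cluster_recovered_within_10nm(self):
        img, locs = self._field([np.array([500.0, 500.0])], 30, 15.0, 1, (1000, 1000))
        cs = detect_clusters(img, locs)
        assert len(cs) == 1
        assert np.linalg.norm(cs.centroids[0] - [500, 500]) < 10.0

    def test_two_separated_clusters(self):
        centers = [np.array([400.0, 500.0]), np.array([700.0, 500.0])]
        img, locs = self._field(centers, 30, 15.0, 2, (1100, 1100))
        cs = detect_clusters(img, locs)
        assert len(cs) == 2

    def test_empty_input(self):
        locs = cn.LocalizationTable(np.zeros(0), np.zeros(0))
        img = cn.render_image(locs, 16.0, (500, 500))
        assert len(detect_clusters(img, locs)) == 0

    def test_centroid_accuracy_over_seeds(self):
        """Well-separated simulated clusters: count exact, centroid error
        below 2 x precision / sqrt(n_locs), over 20 seeds."""
        n, sigma = 30, 15.0
        bound = 2.0 * sigma / np.sqrt(n)
        errors = []
        for seed in range(20):
            centers = [np.array([400.0, 400.0]), np.array([800.0, 700.0])]
            img, locs = self._field(centers, n, sigma, 100 + seed, (1200, 1200))
            cs = detect_clusters(img, locs)
            assert len(cs) == 2
            for c in centers:
                errors.append(np.linalg.norm(cs.centroids - c, axis=1).min())
        assert np.mean(errors) < bound


class TestCellularArea:
    def test_uniform_bright_image_full_mask(self):
        img = cn.RenderedImage(np.ones((256, 256)), 16.0)
        assert cellular_area(img).grid.all()

    def test_zero_image_empty_mask(self):
        img = cn.RenderedImage(np.zeros((256, 256)), 16.0)
        assert not cellular_area(img).grid.any()

    def test_small_bright_speck_removed(self):
        px = np.zeros((256, 256))
        px[100:103, 100:103] = 100.0   # 9 px * 256 nm² = 2304 nm² < 5000
        img = cn.RenderedImage(px, 16.0)
        assert not cellular_area(img).grid.any()

    def test_large_region_survives_area_filter(self):
        px = np.zeros((256, 256))
        px[100:110, 100:110] = 100.0   # 25600 nm² > 5000
        img = cn.RenderedImage(px, 16.0)
        assert cellular_area(img).grid.any()

    def test_monotone_in_intensity(self):
        rng = np.random.default_rng(3)
        base = (rng.random((256, 256)) < 0.02) * 5.0
        extra = base.copy()
        extra[64:192, 64:192] += 3.0
        m1 = cellular_area(cn.RenderedImage(base, 16.0)).grid
        m2 = cellular_area(cn.RenderedImage(extra, 16.0)).grid
        assert (m2 | m1).sum() == m2.sum()   # adding intensity never shrinks
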