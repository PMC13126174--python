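"""FFT periodicity scores, integrated score, and seed region growing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from classinet import periodic1d as p1
from classinet.structures import WindowGrid


def cosine_window(theta_deg: float, period_nm: float, n: int = 64, ps: float = 16.0):
    ii, jj = np.mgrid[0:n, 0:n]
    u = (jj * np.cos(np.radians(theta_deg)) + ii * np.sin(np.radians(theta_deg))) * ps
    return 1.0 + np.cos(2.0 * np.pi * u / period_nm)


class TestAnalyzeWindow:
    @pytest.mark.parametrize(
        "theta,period",
        [(0.0, 192.0), (45.0, 192.0), (90.0, 185.0), (30.0, 200.0),
         (120.0, 170.0), (0.0, 165.0), (0.0, 215.0)],
    )
    def test_orientation_and_period_recovery(self, theta, period):
        spec, scores = p1.analyze_window_1d(cosine_window(theta, period))
        dt = abs(spec.theta - theta) % 180.0
        assert min(dt, 180.0 - dt) < 3.0
        assert abs(spec.d - period) < 5.0
        assert scores.s_integrated > 0.9

    def test_all_zero_window_flagged(self):
        spec, scores = p1.analyze_window_1d(np.zeros((64, 64)))
        assert spec is None
        assert scores.s_integrated == 0.0

    def test_grating_windows_outscore_random_windows(self):
        rng = np.random.default_rng(0)
        s_grating = [
            p1.analyze_window_1d(cosine_window(t, 190.0))[1].s_integrated
            for t in range(0, 180, 20)
        ]
        s_noise = [
            p1.analyze_window_1d(rng.poisson(1.0, (64, 64)).astype(float))[1].s_integrated
            for _ in range(30)
        ]
        assert np.mean(s_grating) > np.mean(s_noise)


class TestIntegratedScore:
    @pytest.mark.parametrize(
        "rg,rl,expected", [(0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.5, 0.5, 0.75)]
    )
    def test_printed_identities(self, rg, rl, expected):
        assert p1.integrated_score(rg, rl) == pytest.approx(expected)

    @settings(deadline=None, max_examples=80)
    @given(
        st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_bounds_monotonicity_symmetry(self, a, b, a2, b2):
        s = p1.integrated_score(a, b)
        assert 0.0 <= s <= 1.0
        assert s >= max(a, b) - 1e-12
        assert s == pytest.approx(p1.integrated_score(b, a))
        if a2 >= a and b2 >= b:
            assert p1.integrated_score(a2, b2) >= s - 1e-12

    def test_negative_inputs_clipped(self):
        assert p1.integrated_score(-0.4, -0.2) == 0.0


def _maps(score, theta, d):
    return p1.OrientationPeriodMap(
        np.asarray(score, float), np.asarray(theta, float),
        np.asarray(d, float), WindowGrid(),
    )


class TestSegment1D:
    def test_uniform_high_score_segments_everything(self):
        shape = (6, 6)
        maps = _maps(np.full(shape, 0.7), np.full(shape, 10.0), np.full(shape, 190.0))
        assert p1.segment_1d(maps).all()

    def test_uniform_subthreshold_score_gives_empty_mask(self):
        shape = (6, 6)
        maps = _maps(np.full(shape, 0.5), np.full(shape, 10.0), np.full(shape, 190.0))
        assert not p1.segment_1d(maps).any()

    def test_orientation_inconsistent_neighbor_not_annexed(self):
        score = np.array([[0.7, 0.5]])
        theta = np.array([[10.0, 40.0]])   # 30 deg apart > 15 deg
        d = np.array([[190.0, 190.0]])
        seg = p1.segment_1d(_maps(score, theta, d), min_region_px=1)
        assert seg[0, 0] and not seg[0, 1]

    def test_consistent_neighbor_annexed(self):
        score = np.array([[0.7, 0.5]])
        theta = np.array([[10.0, 20.0]])
        d = np.array([[190.0, 195.0]])
        seg = p1.segment_1d(_maps(score, theta, d), min_region_px=1)
        assert seg.all()

    def test_orientation_wraps_circularly(self):
        score = np.array([[0.7, 0.5]])
        theta = np.array([[175.0, 5.0]])   # 10 deg apart across the wrap
        d = np.array([[190.0, 190.0]])
        assert p1.segment_1d(_maps(score, theta, d), min_region_px=1).all()

    def test_min_region_size_filter(self):
        score = np.full((5, 5), 0.0)
        score[0, 0] = 0.7
        maps = _maps(score, np.full((5, 5), 10.0), np.full((5, 5), 190.0))
        assert not p1.segment_1d(maps, min_region_px=4).any()


class TestPeriodHistogram:
    def test_single_pixel_distribution(self):
        maps = _maps([[0.7]], [[10.0]], [[188.0]])
        dist = p1.period_histogram(np.array([[True]]), maps)
        assert dist.values.tolist() == [188.0]
        assert dist.mode == pytest.approx(188.0, abs=4.0)

    def test_empty_mask(self):
        maps = _maps([[0.7]], [[10.0]], [[188.0]])
        dist = p1.period_histogram(np.array([[False]]), maps)
        assert dist.values.size == 0 and dist.mode is None
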