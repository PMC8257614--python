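"""Stem geometry: unwrapping, mirroring, spline frame, phi/h, distances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pricklemap as pm
from pricklemap.geometry import OutsideInternodeRange, build_frame

angles = st.floats(min_value=0.0, max_value=359.999, allow_nan=False)


def brute_force_unwrap_step(prev_tc: float, theta: float) -> float:
    """Smallest N with theta + 360 N > prev_tc (enumeration oracle)."""
    for n in range(100):
        if theta + 360.0 * n > prev_tc:
            return theta + 360.0 * n
    raise AssertionError("oracle range exhausted")


class TestUnwrap:
    @pytest.mark.parametrize("thetas, expected", [
        ([10, 150, 290, 70], [10, 150, 290, 430]),
        ([0], [0]),
        ([350, 340], [350, 700]),  # brute force over N in {0,1,2}
        ([100, 100], [100, 460]),  # tie broken by incrementing N
    ])
    def test_examples(self, thetas, expected):
        assert pm.unwrap_leaf_angles(thetas).tolist() == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pm.unwrap_leaf_angles([])

    @given(st.lists(angles, min_size=1, max_size=30))
    def test_round_trip_and_monotone(self, thetas):
        tc = pm.unwrap_leaf_angles(thetas)
        assert np.allclose(np.mod(tc, 360.0), thetas, atol=1e-9)
        assert np.all(np.diff(tc) > 0)
        # agrees with the stepwise enumeration oracle
        expect = [thetas[0]]
        for th in thetas[1:]:
            expect.append(brute_force_unwrap_step(expect[-1], th))
        assert np.allclose(tc, expect)


def _leaf_stem(thetas, heights=None):
    heights = heights or [10.0 * (i + 1) for i in range(len(thetas))]
    return pm.StemRecord("s", [
        pm.OrganObservation(pm.OrganKind.LEAF, th, H)
        for th, H in zip(thetas, heights)])


class TestMirror:
    def test_right_handed_unchanged(self):
        stem = _leaf_stem([0, 140, 280])
        out = pm.mirror_if_left_handed(stem)
        assert not out.mirrored
        assert [o.theta_deg for o in out.organs] == [0, 140, 280]

    def test_left_handed_reflected(self):
        stem = _leaf_stem([0, 220, 80])  # unwrapped divergences 220, 220
        out = pm.mirror_if_left_handed(stem)
        assert out.mirrored
        assert [o.theta_deg for o in out.organs] == [0, 140, 280]

    def test_single_leaf_errors(self):
        with pytest.raises(ValueError, match="insufficient leaves"):
            pm.mirror_if_left_handed(_leaf_stem([10]))

    @given(st.lists(angles, min_size=2, max_size=10, unique=True))
    def test_involution(self, thetas):
        stem = _leaf_stem(thetas)
        once = pm.mirror_if_left_handed(stem)
        twice = pm.mirror_if_left_handed(once)
        assert [o.theta_deg for o in twice.organs] == \
            [o.theta_deg for o in once.organs]
        assert twice.mirrored == once.mirrored


class TestSpline:
    def test_two_point_linear(self):
        fr = pm.fit_phyllotaxis_spline([100, 150], [0, 137.5])
        assert fr(125) == pytest.approx(68.75)
        assert fr(100) == pytest.approx(0.0)

    def test_collinear_cubic_reproduces_line(self):
        fr = pm.fit_phyllotaxis_spline([0, 10, 20, 30], [0, 100, 200, 300])
        # direct polynomial evaluation of the line through the knots
        assert fr(15) == pytest.approx(10.0 * 15, abs=1e-9)
        for H, tc in zip([0, 10, 20, 30], [0, 100, 200, 300]):
            assert fr(H) == pytest.approx(tc, abs=1e-9)

    def test_interpolates_knots_exactly(self):
        H = [0.0, 12.0, 31.0, 55.0, 70.0]
        tc = [5.0, 140.0, 281.0, 430.0, 551.0]
        fr = pm.fit_phyllotaxis_spline(H, tc)
        assert np.allclose(fr(np.array(H)), tc, atol=1e-9)

    @pytest.mark.parametrize("H, tc", [
        ([10, 5], [0, 100]),
        ([0, 10], [100, 50]),
        ([5], [0]),
    ])
    def test_non_monotone_errors(self, H, tc):
        with pytest.raises(ValueError):
            pm.fit_phyllotaxis_spline(H, tc)


class TestPhiH:
    @pytest.fixture
    def frame(self):
        # spline value at H=125 is exactly 120 by linearity
        return pm.fit_phyllotaxis_spline([100, 150], [95, 145])

    @pytest.mark.parametrize("theta, expected", [
        (200, 80.0),
        (60, -60.0),
        (20, 260.0),  # raw -100 < -90 so N increments once
    ])
    def test_phi_examples(self, theta, expected, frame):
        assert pm.compute_phi(theta, 125.0, frame) == pytest.approx(expected)

    @given(angles, st.integers(min_value=-3, max_value=3))
    def test_phi_range_and_360_invariance(self, theta, k):
        frame = pm.fit_phyllotaxis_spline([0, 50], [0, 137.5])
        phi = pm.compute_phi(theta, 25.0, frame)
        assert -90.0 <= phi < 270.0
        assert pm.compute_phi(theta + 360.0 * k, 25.0, frame) == \
            pytest.approx(phi)
        # brute force: the in-range candidate is unique
        raw = theta - float(frame(25.0))
        candidates = [raw + 360 * n for n in range(-3, 4)
                      if -90 <= raw + 360 * n < 270]
        assert candidates == [pytest.approx(phi)]

    def test_phi_outside_span_errors(self, frame):
        with pytest.raises(OutsideInternodeRange):
            pm.compute_phi(0.0, 99.0, frame)

    def test_h_examples(self):
        fr = pm.fit_phyllotaxis_spline([100, 150, 180], [0, 137.5, 275])
        assert pm.compute_h(130, fr) == (pytest.approx(0.6), 0)
        assert pm.compute_h(100, fr) == (0.0, 0)       # node -> upper internode
        assert pm.compute_h(150, fr) == (0.0, 1)       # interior node
        assert pm.compute_h(180, fr) == (1.0, 1)       # topmost node


class TestDivergence:
    def test_constant_spiral(self):
        fr = pm.fit_phyllotaxis_spline([0, 10, 20], [0, 137.5, 275.0])
        assert pm.divergence_angles(fr).tolist() == [137.5, 137.5]

    def test_large_deviation_passthrough(self):
        fr = pm.fit_phyllotaxis_spline([0, 10], [0, 290])
        assert pm.divergence_angles(fr).tolist() == [290]


class TestNearestDistances:
    def test_purely_axial(self):
        d = pm.nearest_prickle_distances([(10, 100), (10, 107)], 3.0)
        assert d.tolist() == [7.0, 7.0]

    def test_purely_circumferential(self):
        d = pm.nearest_prickle_distances([(0, 50), (180, 50)], 2.0 / math.pi)
        assert np.allclose(d, [2.0, 2.0])

    def test_fewer_than_two_empty(self):
        assert pm.nearest_prickle_distances([(0, 0)], 5.0).size == 0

    @given(st.lists(st.tuples(angles,
                              st.floats(min_value=0, max_value=500)),
                    min_size=2, max_size=20))
    def test_matches_brute_force(self, pts):
        r = 5.0
        d = pm.nearest_prickle_distances(pts, r)
        for i, (thi, Hi) in enumerate(pts):
            best = min(
                math.hypot(Hi - Hj,
                           r * abs(math.remainder(math.radians(thi - thj),
                                                  2 * math.pi)))
                for j, (thj, Hj) in enumerate(pts) if j != i)
            assert d[i] == pytest.approx(best, rel=1e-12, abs=1e-12)


class TestLayerSplit:
    def _pp(self, H, phi=0.0):
        return pm.ProcessedPrickle(phi_deg=phi, h=0.5, H_mm=H,
                                   internode_index=0, source_index=0)

    def test_one_per_layer(self):
        layers = pm.layer_split([self._pp(50), self._pp(150), self._pp(250)],
                                H_top=300)
        assert [len(l) for l in layers] == [1, 1, 1]

    def test_boundary_goes_to_middle(self):
        layers = pm.layer_split([self._pp(100)], H_top=300)
        assert [len(l) for l in layers] == [0, 1, 0]

    def test_empty(self):
        assert pm.layer_split([], H_top=100) == ([], [], [])


class TestProcessStem:
    def test_round_trip_theta_reconstruction(self, simple_stem):
        df = pm.process_stem(simple_stem)
        frame = build_frame(pm.mirror_if_left_handed(simple_stem))
        originals = {p.H_mm: p.theta_deg for p in simple_stem.prickles}
        for row in df.itertuples():
            theta = (float(frame(row.H_mm)) + row.phi_deg) % 360.0
            assert theta == pytest.approx(originals[row.H_mm], abs=1e-9)
            assert -90 <= row.phi_deg < 270
            assert 0 <= row.h <= 1

    def test_out_of_span_prickles_skipped(self, caplog):
        organs = [
            pm.OrganObservation(pm.OrganKind.PRICKLE, 10.0, 5.0),  # below span
            pm.OrganObservation(pm.OrganKind.LEAF, 0.0, 10.0),
            pm.OrganObservation(pm.OrganKind.PRICKLE, 90.0, 15.0),
            pm.OrganObservation(pm.OrganKind.LEAF, 140.0, 20.0),
        ]
        with caplog.at_level("WARNING"):
            df = pm.process_stem(pm.StemRecord("s", organs))
        assert len(df) == 1
        assert "skipped 1" in caplog.text

    def test_d_pp_column(self, simple_stem):
        df = pm.process_stem(simple_stem, stem_radius_mm=5.0)
        expected = pm.nearest_prickle_distances(
            [(p.theta_deg, p.H_mm) for p in simple_stem.prickles], 5.0)
        assert np.allclose(df["d_pp_mm"], expected)
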