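"""Chamber pressure-volume mechanics: bounding relations and activation."""

import math

import pytest
from hypothesis import given, strategies as st

from hfpefsim.chambers import (ChamberParams, activation, activation_rate,
                               chamber_pressure, edpvr_pressure, edpvr_volume,
                               espvr_pressure)
from hfpefsim.parameters import group_preset


@pytest.fixture(scope="module")
def lv1():
    return group_preset(1).lv


@pytest.fixture(scope="module")
def atrium():
    return group_preset(1).la


class TestESPVR:
    def test_vertex_and_root(self, lv1):
        assert espvr_pressure(140.0, lv1) == pytest.approx(220.0)
        assert espvr_pressure(0.0, lv1) == pytest.approx(0.0)

    def test_parabolic_midpoint(self, lv1):
        # direct evaluation: 220 * (1 - (70/140)^2)
        assert espvr_pressure(70.0, lv1) == pytest.approx(165.0)

    def test_clipped_beyond_far_root(self, lv1):
        assert espvr_pressure(2 * 140.0 + 10.0, lv1) == 0.0

    def test_rejects_bad_volume(self, lv1):
        with pytest.raises(ValueError):
            espvr_pressure(-1.0, lv1)
        with pytest.raises(ValueError):
            espvr_pressure(float("nan"), lv1)

    def test_atrium_has_no_espvr(self, atrium):
        with pytest.raises(ValueError):
            espvr_pressure(50.0, atrium)


class TestEDPVR:
    def test_zero_at_zero_volume(self, lv1):
        assert edpvr_pressure(0.0, lv1) == 0.0

    def test_atrial_anchor_point(self, atrium):
        # enlarged atrium: ~15 mmHg at 90 ml
        p = edpvr_pressure(90.0, atrium)
        assert p == pytest.approx(14.56, rel=0.01)

    def test_lv_power_law(self, lv1):
        # alpha * 100**beta with the Group 1 coefficients
        expected = 5.5742e-6 * 100.0 ** 3.3186
        assert edpvr_pressure(100.0, lv1) == pytest.approx(expected)
        assert expected == pytest.approx(24.2, abs=0.1)

    def test_inverse_round_trip(self, lv1, atrium):
        for params, v in ((lv1, 87.3), (atrium, 60.0)):
            p = edpvr_pressure(v, params)
            assert edpvr_volume(p, params) == pytest.approx(v, rel=1e-9)

    def test_rejects_negative_volume(self, lv1):
        with pytest.raises(ValueError):
            edpvr_pressure(-5.0, lv1)


class TestActivation:
    def test_peak_is_one(self, lv1):
        period = 0.8
        duration = 0.3 * math.sqrt(period)
        assert activation(duration, period, lv1) == pytest.approx(1.0)

    def test_diastasis_is_negligible(self, lv1):
        assert activation(0.75, 0.8, lv1) < 1e-3

    def test_relaxation_time_constant(self, lv1):
        # two points on the relaxation limb 54 ms apart have ratio e^-1
        period = 0.8
        t1 = 0.3 * math.sqrt(period) + 0.02
        e1 = activation(t1, period, lv1)
        e2 = activation(t1 + lv1.tau_relax, period, lv1)
        assert e2 / e1 == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_rejects_bad_inputs(self, lv1):
        with pytest.raises(ValueError):
            activation(0.1, 0.0, lv1)
        with pytest.raises(ValueError):
            activation(0.9, 0.8, lv1)

    @given(ct=st.floats(0.0, 0.799), period=st.just(0.8))
    def test_bounded_unit_interval(self, ct, period):
        e = activation(ct, period, group_preset(1).lv)
        assert 0.0 <= e <= 1.0

    def test_rate_matches_finite_difference(self, lv1):
        period, h = 0.8, 1e-6
        for ct in (0.05, 0.12, 0.2, 0.35, 0.5):
            num = (activation(ct + h, period, lv1)
                   - activation(ct - h, period, lv1)) / (2 * h)
            assert activation_rate(ct, period, lv1) == pytest.approx(num, rel=1e-3, abs=1e-3)


class TestChamberPressure:
    def test_limits_reduce_to_bounding_relations(self, lv1):
        v = 90.0
        assert chamber_pressure(v, 0.0, lv1) == pytest.approx(edpvr_pressure(v, lv1))
        assert chamber_pressure(v, 1.0, lv1) == pytest.approx(espvr_pressure(v, lv1))

    def test_midpoint_interpolation(self, lv1):
        # direct evaluation of (ESPVR(100) + EDPVR(100)) / 2 with the
        # Group 1 coefficients: (202.0 + 24.2) / 2
        expected = 0.5 * (espvr_pressure(100.0, lv1) + edpvr_pressure(100.0, lv1))
        assert chamber_pressure(100.0, 0.5, lv1) == pytest.approx(expected)
        assert expected == pytest.approx(113.1, abs=0.2)

    def test_atrial_kick_adds_linear_elastance(self, atrium):
        v = 85.0
        passive = edpvr_pressure(v, atrium)
        assert chamber_pressure(v, 0.0, atrium) == pytest.approx(passive)
        full = chamber_pressure(v, 1.0, atrium)
        assert full == pytest.approx(passive + atrium.kick_elastance * v)

    @given(v=st.floats(0.0, 140.0), e=st.floats(0.0, 1.0))
    def test_bounded_by_pv_relations(self, v, e):
        lv = group_preset(1).lv
        p = chamber_pressure(v, e, lv)
        assert edpvr_pressure(v, lv) - 1e-9 <= p <= espvr_pressure(v, lv) + 1e-9

    def test_monotone_in_volume_below_vertex(self, lv1):
        for e in (0.0, 0.3, 0.7, 1.0):
            values = [chamber_pressure(v, e, lv1) for v in range(0, 141, 5)]
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_rejects_bad_activation(self, lv1):
        with pytest.raises(ValueError):
            chamber_pressure(100.0, 1.2, lv1)


class TestChamberParamsValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ChamberParams(alpha=-1.0, beta=3.0)
        with pytest.raises(ValueError):
            ChamberParams(alpha=1e-5, beta=0.9)
        with pytest.raises(ValueError):
            ChamberParams(alpha=1e-5, beta=3.0, v_sys=100.0)  # p_sys missing
        with pytest.raises(ValueError):
            ChamberParams(alpha=1e-5, beta=3.0, v_sys=0.0, p_sys=100.0)
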