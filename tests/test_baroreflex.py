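"""Heart-rate law, effector dynamics and the exercise trigger."""

import math

import pytest
from hypothesis import given, strategies as st

from hfpefsim.baroreflex import (BaroreflexParams, BaroreflexState,
                                 apply_exercise, group_baroreflex, heart_rate,
                                 pressure_error_for_heart_rate,
                                 update_autonomic_state)
from hfpefsim.parameters import group_preset


@pytest.fixture(scope="module")
def baro1():
    return group_baroreflex(1)


class TestHeartRateLaw:
    def test_neutral_point(self, baro1):
        # dP = 0: period is the midpoint of the sigmoid
        assert heart_rate(0.0, baro1) == pytest.approx(60.0 / 0.825, rel=1e-6)
        assert heart_rate(0.0, baro1) == pytest.approx(72.7, abs=0.05)

    def test_hypotension_limit(self, baro1):
        # MAP far below the set point: period saturates at t_min
        assert heart_rate(1e4, baro1) == pytest.approx(200.0)

    def test_hypertension_limit(self, baro1):
        assert heart_rate(-1e4, baro1) == pytest.approx(60.0 / 1.35, rel=1e-6)

    @given(dp=st.floats(-500, 500))
    def test_bounded_by_sigmoid_range(self, dp):
        b = group_baroreflex(1)
        hr = heart_rate(dp, b)
        assert 60.0 / b.t_max - 1e-9 <= hr <= 60.0 / b.t_min + 1e-9

    @given(dp=st.floats(-100, 100))
    def test_monotone_in_pressure_error(self, dp):
        b = group_baroreflex(1)
        assert heart_rate(dp + 1.0, b) > heart_rate(dp, b)

    def test_inverse_round_trip(self, baro1):
        for hr in (60.0, 76.5, 120.0):
            dp = pressure_error_for_heart_rate(hr, baro1)
            assert heart_rate(dp, baro1) == pytest.approx(hr, rel=1e-9)

    def test_rejects_non_finite_error(self, baro1):
        with pytest.raises(ValueError):
            heart_rate(float("nan"), baro1)


class TestEffectors:
    def test_neutral_at_resting_offset(self, baro1):
        state = BaroreflexState(filtered_map=93.4, svr_scale=1.0,
                                volume_shift=0.0)
        new = update_autonomic_state(baro1.dp0, baro1, state, dt=1e6)
        assert new.svr_scale == pytest.approx(1.0)
        assert new.volume_shift == pytest.approx(0.0)

    def test_one_percent_resistance_per_mmhg(self):
        # +1 mmHg of pressure error commands a 1% resistance rise
        b = BaroreflexParams(t_min=0.3, t_max=1.35, g_hr=0.0983,
                             map_setpoint=93.4)
        state = BaroreflexState(filtered_map=93.4)
        new = update_autonomic_state(1.0, b, state, dt=1e6)
        assert new.svr_scale == pytest.approx(1.01)

    def test_volume_gain_and_saturation(self):
        b = BaroreflexParams(t_min=0.3, t_max=1.35, g_hr=0.0983,
                             map_setpoint=93.4, vol_gain=130.0)
        state = BaroreflexState(filtered_map=93.4)
        # 130 ml/mmHg x 10 mmHg commanded shift
        new = update_autonomic_state(10.0, b, state, dt=1e6)
        assert new.volume_shift == pytest.approx(1300.0)
        # far outside the reserve: clamped
        new = update_autonomic_state(100.0, b, state, dt=1e6)
        assert new.volume_shift == pytest.approx(b.volume_shift_limit)

    def test_first_order_relaxation(self, baro1):
        state = BaroreflexState(filtered_map=90.0)
        dt = baro1.tau_effector
        new = update_autonomic_state(baro1.dp0 + 10.0, baro1, state, dt=dt)
        # one time constant: ~63% of the commanded change
        assert new.volume_shift == pytest.approx(
            1300.0 * (1 - math.exp(-1.0)), rel=1e-6)


class TestExerciseTrigger:
    def test_resistance_drop_and_setpoint_rise(self):
        baro, circ = group_baroreflex(2), group_preset(2)
        ex_baro, ex_circ = apply_exercise(baro, circ, 2)
        assert ex_circ.rart_ub == pytest.approx(3.0453 * 0.55)
        assert ex_circ.rart_ub == pytest.approx(1.6749, abs=1e-3)
        assert ex_circ.rart_lb == pytest.approx(1.2181 * 0.55)
        assert ex_baro.map_setpoint == pytest.approx(baro.map_setpoint * 1.30)

    def test_group1_setpoint_rise(self):
        baro, circ = group_baroreflex(1), group_preset(1)
        ex_baro, _ = apply_exercise(baro, circ, 1)
        assert ex_baro.map_setpoint == pytest.approx(baro.map_setpoint * 1.32)

    def test_applying_twice_is_rejected(self):
        baro, circ = group_baroreflex(1), group_preset(1)
        ex_baro, ex_circ = apply_exercise(baro, circ, 1)
        with pytest.raises(ValueError):
            apply_exercise(ex_baro, ex_circ, 1)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            apply_exercise(group_baroreflex(1), group_preset(1), 3)

    def test_lungs_untouched_by_exercise(self):
        baro, circ = group_baroreflex(1), group_preset(1)
        _, ex_circ = apply_exercise(baro, circ, 1)
        assert ex_circ.rart_ll == circ.rart_ll
        assert ex_circ.rven_ub == circ.rven_ub


class TestPresets:
    def test_resting_heart_rate_on_sigmoid(self):
        # the resting offset dp0 puts the group's resting HR on the law
        for group, hr in ((1, 76.5), (2, 70.0)):
            b = group_baroreflex(group)
            assert heart_rate(b.dp0, b) == pytest.approx(hr, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            BaroreflexParams(t_min=0.5, t_max=0.4, g_hr=0.1, map_setpoint=90.0)
        with pytest.raises(ValueError):
            BaroreflexParams(t_min=0.3, t_max=1.0, g_hr=-0.1, map_setpoint=90.0)
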