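"""Baroreflex autoregulation and the exercise trigger.

A single afferent signal -- the difference ``dP`` between the arterial
set point and the (low-pass filtered) mean arterial pressure -- drives
three effectors:

* heart period, through a bounded sigmoid law

      HR = 60 / { [T_min + T_max * exp(-dP * G_HR)] / [1 + exp(-dP * G_HR)] }

  The exponent carries ``-dP`` so that pressure below the set point
  (dP > 0) shortens the period toward ``T_min`` (tachycardia).

* systemic arterial resistance, scaled by 1% per mmHg of pressure error;

* stressed venous volume, shifted from the unstressed reserve by
  ``vol_gain`` ml per mmHg of pressure error (130 ml/mmHg in Group 1,
  75 ml/mmHg in Group 2), raising the effective filling pressure.

All effectors act through first-order dynamics with a common time
constant; only the converged periodic state is analysed.  The resistance
and volume effectors are referenced to the resting operating point: the
set point sits ``dP0`` mmHg above the resting arterial pressure (the
offset needed for the resting heart rate on the sigmoid), and effector
commands respond to ``dP - dP0`` so that the calibrated resting parameter
set is the effector-neutral equilibrium.

Exercise is triggered by dropping systemic arterial resistance by 45% and
raising the set point by 32% (Group 1) or 30% (Group 2); the reflex then
closes the loop, raising heart rate, restoring arterial pressure and
recruiting stressed volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .parameters import CirculationParams

# engine packing indices
BR_TMIN, BR_TMAX, BR_GHR, BR_SETPT, BR_SVR_GAIN, BR_VOL_GAIN = 0, 1, 2, 3, 4, 5
BR_DP0, BR_VOL_MAX, BR_TAU_EFF, BR_TAU_MAP, BR_ON, BR_FIXED_T = 6, 7, 8, 9, 10, 11
BR_PULM_FRAC, BR_SVR_MAX = 12, 13
NBR = 14

#: Saturation of the commanded stressed-volume shift (ml); bounded by the
#: physiological unstressed venous reserve.
VOLUME_SHIFT_LIMIT = 2000.0

#: First-order effector / afferent-filter time constants (s).
TAU_EFFECTOR = 2.0
TAU_MAP_FILTER = 2.0

#: Fraction of the recruited stressed volume entering the pulmonary venous
#: pool (the remainder loads the systemic veins in proportion to their
#: compliances); mobilized reserves distribute across the whole venous bed.
PULMONARY_SHIFT_FRACTION = {1: 0.5, 2: 0.25}


@dataclass
class BaroreflexParams:
    """Gains and set points of the reflex arcs for one phenotype."""

    t_min: float
    t_max: float
    g_hr: float
    map_setpoint: float
    svr_gain: float = 0.01          # fractional resistance change per mmHg
    vol_gain: float = 130.0         # ml of stressed volume per mmHg
    exercise_svr_drop: float = 0.45
    exercise_setpoint_rise: float = 0.32
    dp0: float = 0.0                # resting pressure error on the HR sigmoid
    volume_shift_limit: float = VOLUME_SHIFT_LIMIT
    tau_effector: float = TAU_EFFECTOR
    tau_map: float = TAU_MAP_FILTER
    pulmonary_shift_fraction: float = 0.25
    svr_scale_max: float = 10.0     # upward saturation of the resistance effector
    exercise: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")
        if not (self.g_hr > 0):
            raise ValueError("g_hr must be > 0")
        for name in ("svr_gain", "vol_gain", "volume_shift_limit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def vector(self, enabled: bool = True, fixed_period: float = 0.8) -> np.ndarray:
        vec = np.zeros(NBR, dtype=np.float64)
        vec[BR_TMIN] = self.t_min
        vec[BR_TMAX] = self.t_max
        vec[BR_GHR] = self.g_hr
        vec[BR_SETPT] = self.map_setpoint
        vec[BR_SVR_GAIN] = self.svr_gain
        vec[BR_VOL_GAIN] = self.vol_gain
        vec[BR_DP0] = self.dp0
        vec[BR_VOL_MAX] = self.volume_shift_limit
        vec[BR_TAU_EFF] = self.tau_effector
        vec[BR_TAU_MAP] = self.tau_map
        vec[BR_ON] = 1.0 if enabled else 0.0
        vec[BR_FIXED_T] = fixed_period
        vec[BR_PULM_FRAC] = self.pulmonary_shift_fraction
        vec[BR_SVR_MAX] = self.svr_scale_max
        return vec


@dataclass
class BaroreflexState:
    """Slow effector states carried alongside the hemodynamic state."""

    filtered_map: float
    svr_scale: float = 1.0
    volume_shift: float = 0.0
    heart_period: float = 0.8

    def __post_init__(self) -> None:
        if self.heart_period <= 0:
            raise ValueError("heart_period must be > 0")


def heart_period(dp: float, params: BaroreflexParams) -> float:
    """Heart period (s) from the bounded sigmoid law; dP in mmHg."""
    if not math.isfinite(dp):
        raise ValueError("dp must be finite")
    x = -dp * params.g_hr
    # numerically safe logistic blending between t_min and t_max
    if x > 50.0:
        w = 1.0
    elif x < -50.0:
        w = 0.0
    else:
        e = math.exp(x)
        w = e / (1.0 + e)
    return params.t_min + (params.t_max - params.t_min) * w


def heart_rate(dp: float, params: BaroreflexParams) -> float:
    """Heart rate (bpm); monotone increasing in dP, bounded in
    [60/t_max, 60/t_min]."""
    return 60.0 / heart_period(dp, params)


def pressure_error_for_heart_rate(hr: float, params: BaroreflexParams) -> float:
    """Invert the HR law: the dP (mmHg) that yields ``hr`` (bpm)."""
    t = 60.0 / hr
    if not (params.t_min < t < params.t_max):
        raise ValueError("heart rate outside the open sigmoid range")
    w = (t - params.t_min) / (params.t_max - params.t_min)
    return -math.log(w / (1.0 - w)) / params.g_hr


def update_autonomic_state(
    dp: float, params: BaroreflexParams, state: BaroreflexState, dt: float = 1.0
) -> BaroreflexState:
    """Advance the three effectors by one first-order relaxation step.

    Reference implementation of the effector dynamics used by the
    compiled engine; the resistance and volume commands respond to the
    recentred error ``dp - dp0``.
    """
    dpe = dp - params.dp0
    svr_target = min(max(1.0 + params.svr_gain * dpe, 0.3), params.svr_scale_max)
    vol_target = float(
        np.clip(params.vol_gain * dpe, -params.volume_shift_limit,
                params.volume_shift_limit)
    )
    a = 1.0 - math.exp(-dt / params.tau_effector)
    return BaroreflexState(
        filtered_map=state.filtered_map,
        svr_scale=state.svr_scale + a * (svr_target - state.svr_scale),
        volume_shift=state.volume_shift + a * (vol_target - state.volume_shift),
        heart_period=heart_period(dp, params),
    )


# ---------------------------------------------------------------------------
# presets and the exercise trigger
# ---------------------------------------------------------------------------

#: Resting arterial operating pressure of each calibrated phenotype (mmHg).
RESTING_MAP = {1: 93.4, 2: 108.0}
#: Resting heart rate of each phenotype (bpm).
RESTING_HR = {1: 76.5, 2: 70.0}

_SIGMOID = {1: dict(t_min=0.3, t_max=1.35, g_hr=0.0983),
            2: dict(t_min=0.5, t_max=1.3, g_hr=0.1075)}
_VOL_GAIN = {1: 130.0, 2: 75.0}
_SETPT_RISE = {1: 0.32, 2: 0.30}
#: Calibration trim on the resting set point (mmHg); raises the Group 1
#: operating pressure slightly so the exercise response recruits enough
#: volume for the reported exercise filling pressures.
_SETPOINT_TRIM = {1: 2.0, 2: 0.0}


def group_baroreflex(group: int) -> BaroreflexParams:
    """Baroreflex preset for phenotype group 1 or 2 (resting configuration).

    The resting set point is the resting arterial pressure plus the
    sigmoid offset ``dp0`` required to sustain the resting heart rate.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    sig = _SIGMOID[group]
    probe = BaroreflexParams(map_setpoint=100.0, vol_gain=_VOL_GAIN[group],
                             exercise_setpoint_rise=_SETPT_RISE[group],
                             pulmonary_shift_fraction=PULMONARY_SHIFT_FRACTION[group],
                             **sig)
    dp0 = pressure_error_for_heart_rate(RESTING_HR[group], probe)
    return replace(probe, map_setpoint=RESTING_MAP[group] + dp0
                   + _SETPOINT_TRIM[group], dp0=dp0)


def apply_exercise(
    params: BaroreflexParams, circ: CirculationParams, group: int
) -> Tuple[BaroreflexParams, CirculationParams]:
    """Switch a resting configuration to the exercise condition.

    Systemic arterial resistances drop by ``exercise_svr_drop`` (45%) and
    the arterial set point rises by 32% / 30% (group 1 / 2); applying the
    trigger twice is rejected.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    if params.exercise:
        raise ValueError("exercise already applied to this configuration")
    keep = 1.0 - params.exercise_svr_drop
    new_circ = replace(
        circ, rart_ub=circ.rart_ub * keep, rart_lb=circ.rart_lb * keep
    )
    new_baro = replace(
        params,
        map_setpoint=params.map_setpoint * (1.0 + params.exercise_setpoint_rise),
        exercise=True,
    )
    return new_baro, new_circ
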