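"""Device-therapy models: interatrial shunt, rotary pump, co-pulsating chamber.

Four strategies are modelled on top of the closed loop:

* ``iasd`` -- interatrial shunt device: a fixed linear orifice resistance
  (0.1 mmHg*s/ml, roughly an 8 mm shunt) between the left and right
  atrium; flow is bidirectional and follows the instantaneous pressure
  gradient.

* ``rbp_lv`` / ``rbp_la`` -- a HeartMate-3-class continuous-flow rotary
  blood pump drawing from the LV apex or the left atrium and returning to
  the ascending aorta.  The static pressure head follows an
  affinity-law-consistent characteristic

      H(omega, q) = a * omega^2 - b * q * |q|        [mmHg]

  with omega in krpm and q in l/min, in series with a blood-column
  inertance so that instantaneous flow obeys
  ``L_pump * dq/dt = P_in + H - P_out``.  Backflow (q < 0) is admitted,
  as in the physical device.

* ``copulse`` -- a valveless 30 ml compliance chamber on a single LV-apex
  cannula operating in co-pulsation: the chamber empties into the LV with
  the systolic activation rise (lagging it by a short drive delay, so the
  tail of the ejected volume arrives around aortic valve closure) and
  refills from the LV slowly over the whole diastolic window.  Net
  cannula flow over any full beat is zero; per-minute displaced volume is
  stroke x HR, which is why unloading grows with heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .chambers import ChamberParams, SYSTOLIC_INTERVAL_FACTOR

# engine packing indices
DV_KIND, DV_IASD_R, DV_SPEED, DV_PA, DV_PB, DV_PC = 0, 1, 2, 3, 4, 5
DV_LPUMP, DV_STROKE, DV_COP_RC, DV_COP_LC = 6, 7, 8, 9
NDV = 10

KINDS = ("none", "iasd", "rbp_lv", "rbp_la", "copulse")
_KIND_CODE = {k: i for i, k in enumerate(KINDS)}

#: Interatrial shunt resistance (mmHg*s/ml), ~8 mm orifice.
IASD_RESISTANCE = 0.1

#: Co-pulsating chamber priming / stroke volume (ml) and cannula elements.
COPULSE_STROKE = 30.0
COPULSE_CANNULA_R = 0.01
COPULSE_CANNULA_L = 1e-4

#: Rotary pump operating envelope (rpm).
PUMP_SPEED_MIN = 3000.0
PUMP_SPEED_MAX = 9000.0


@dataclass(frozen=True)
class PumpParams:
    """Static and dynamic coefficients of the rotary pump model.

    ``a`` (mmHg/krpm^2) scales the shut-off head with speed squared (the
    affinity law); ``b`` (mmHg/(l/min)^2) and ``c`` (mmHg/(l/min)) set the
    head loss with flow; ``inertance`` (mmHg*s^2/ml) lumps the fluid and
    rotor-control dynamics of the pump and its cannulae.  The defaults
    describe a HeartMate 3-class centrifugal pump with the cannulae
    losses folded into the flow coefficient, chosen so the clinical
    operating points (4-6 krpm against 60-90 mmHg) are reproduced.
    """

    a: float = 3.6
    b: float = 1.5
    c: float = 0.0
    inertance: float = 0.05


HM3 = PumpParams()


@dataclass
class DeviceConfig:
    """Tagged device selection: exactly one therapy (or none) is active."""

    kind: str = "none"
    iasd_resistance: float = IASD_RESISTANCE
    pump_speed: Optional[float] = None          # rpm
    pump: PumpParams = HM3
    copulse_stroke: float = COPULSE_STROKE
    copulse_cannula_r: float = COPULSE_CANNULA_R
    copulse_cannula_l: float = COPULSE_CANNULA_L

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown device kind {self.kind!r}; one of {KINDS}")
        if self.kind == "iasd" and not (self.iasd_resistance > 0):
            raise ValueError("iasd_resistance must be > 0")
        if self.kind in ("rbp_lv", "rbp_la"):
            if self.pump_speed is None:
                raise ValueError("pump_speed (rpm) is required for a rotary pump")
            if not (PUMP_SPEED_MIN <= self.pump_speed <= PUMP_SPEED_MAX):
                raise ValueError(
                    f"pump_speed {self.pump_speed} rpm outside "
                    f"[{PUMP_SPEED_MIN:.0f}, {PUMP_SPEED_MAX:.0f}]"
                )
        if self.kind == "copulse":
            if not (0 < self.copulse_stroke <= COPULSE_STROKE):
                raise ValueError(
                    f"copulse stroke must lie in (0, {COPULSE_STROKE}] ml "
                    "(chamber priming volume) without reconfiguration"
                )

    def vector(self) -> np.ndarray:
        vec = np.zeros(NDV, dtype=np.float64)
        vec[DV_KIND] = _KIND_CODE[self.kind]
        vec[DV_IASD_R] = self.iasd_resistance
        vec[DV_SPEED] = (self.pump_speed or 0.0) / 1000.0   # krpm
        vec[DV_PA] = self.pump.a
        vec[DV_PB] = self.pump.b
        vec[DV_PC] = self.pump.c
        vec[DV_LPUMP] = self.pump.inertance
        vec[DV_STROKE] = self.copulse_stroke
        vec[DV_COP_RC] = self.copulse_cannula_r
        vec[DV_COP_LC] = self.copulse_cannula_l
        return vec


def no_device() -> DeviceConfig:
    return DeviceConfig(kind="none")


def iasd(resistance: float = IASD_RESISTANCE) -> DeviceConfig:
    return DeviceConfig(kind="iasd", iasd_resistance=resistance)


def rbp(inflow: str, speed_rpm: float, pump: PumpParams = HM3) -> DeviceConfig:
    if inflow not in ("lv", "la"):
        raise ValueError("inflow must be 'lv' or 'la'")
    return DeviceConfig(kind=f"rbp_{inflow}", pump_speed=speed_rpm, pump=pump)


def copulse(stroke: float = COPULSE_STROKE) -> DeviceConfig:
    return DeviceConfig(kind="copulse", copulse_stroke=stroke)


# ---------------------------------------------------------------------------
# element laws (reference implementations mirrored by the compiled engine)
# ---------------------------------------------------------------------------

def iasd_flow(lap: float, rap: float, r: float = IASD_RESISTANCE) -> float:
    """Shunt flow LA -> RA (ml/s); negative when RAP exceeds LAP."""
    if not (r > 0):
        raise ValueError("shunt resistance must be > 0")
    return (lap - rap) / r


def pump_pressure_head(speed_rpm: float, flow_mls: float,
                       pump: PumpParams = HM3) -> float:
    """Static pump pressure head (mmHg) at a given speed and flow.

    Monotone decreasing in flow; the head at zero flow is the shut-off
    head a*omega^2, and heads above it imply reverse (negative) flow.
    """
    if not (PUMP_SPEED_MIN <= speed_rpm <= PUMP_SPEED_MAX):
        raise ValueError("speed outside the pump operating envelope")
    omega = speed_rpm / 1000.0
    q = flow_mls * 0.06  # l/min
    return pump.a * omega * omega - pump.b * q * abs(q) - pump.c * q


def pump_static_flow(speed_rpm: float, head_mmhg: float,
                     pump: PumpParams = HM3) -> float:
    """Invert the static characteristic: flow (ml/s) at a given head."""
    omega = speed_rpm / 1000.0
    shutoff = pump.a * omega * omega
    if pump.b == 0 and pump.c == 0:
        raise ValueError("zero-slope characteristic has no unique flow")
    # solve head = shutoff - b q|q| - c q  for q (l/min)
    d = shutoff - head_mmhg
    if pump.b == 0:
        q = d / pump.c
    else:
        sign = 1.0 if d >= 0 else -1.0
        q = sign * (-pump.c + math.sqrt(pump.c * pump.c + 4 * pump.b * abs(d))) / (2 * pump.b)
    return q / 0.06


#: Drive delay of the co-pulsation actuator behind native systole (s).
COPULSE_DRIVE_DELAY = 0.07

#: Peak-activation plateau of the ventricular drive waveform (s); shared
#: with the circulation engine.
SYSTOLIC_PLATEAU = 0.07


def copulse_drive(cycle_time: float, period: float) -> Tuple[float, float]:
    """Normalized chamber emptying fraction w(t) and its rate dw/dt.

    ``w`` rises with the (delayed) systolic activation ramp, holds at 1
    through the plateau and returns to 0 along a half-cosine spanning the
    remaining diastole, so the chamber refills gently instead of sucking
    the relaxing ventricle dry.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    tc = float(cycle_time) - COPULSE_DRIVE_DELAY
    if tc < 0.0:
        tc += period
    rise = SYSTOLIC_INTERVAL_FACTOR * math.sqrt(period) - SYSTOLIC_PLATEAU
    t0 = rise + SYSTOLIC_PLATEAU
    if tc < rise:
        sw = math.sin(0.5 * math.pi * tc / rise)
        return sw * sw, 0.5 * math.pi / rise * math.sin(math.pi * tc / rise)
    if tc < t0:
        return 1.0, 0.0
    x = (tc - t0) / (period - t0)
    cw = math.cos(0.5 * math.pi * x)
    return cw * cw, -0.5 * math.pi / (period - t0) * math.sin(math.pi * x)


def copulse_flow(cycle_time: float, period: float, lv_params: ChamberParams,
                 config: DeviceConfig) -> Tuple[float, float]:
    """Instantaneous cannula flow into the LV and chamber volume.

    The chamber volume is ``stroke * (1 - w(t))`` with ``w`` the drive
    waveform of :func:`copulse_drive`, so the cannula flow is
    ``stroke * dw/dt`` (positive into the LV during systole) and
    integrates to zero over a beat.  Returns ``(flow ml/s, chamber
    volume ml)``.
    """
    if config.kind != "copulse":
        raise ValueError("config is not a copulse device")
    w, dw = copulse_drive(cycle_time, period)
    return config.copulse_stroke * dw, config.copulse_stroke * (1.0 - w)


# ---------------------------------------------------------------------------
# pump speed selection
# ---------------------------------------------------------------------------

@dataclass
class SpeedSelection:
    """Result of the speed search: chosen speed and criterion evaluations."""

    speed_rpm: Optional[float]
    feasible: bool
    mean_lap: Optional[float] = None
    min_pump_flow: Optional[float] = None   # l/min
    evaluations: tuple = ()


def select_pump_speed(
    group: int,
    inflow: str,
    pump: PumpParams = HM3,
    lap_limit: float = 10.0,
    speed_grid: float = 100.0,
    backflow_tolerance: float = 0.05,
) -> SpeedSelection:
    """Smallest speed on a 100-rpm grid meeting both resting criteria.

    Criteria, evaluated on the converged resting baseline of the given
    phenotype group: beat-mean LAP below ``lap_limit`` (10 mmHg) and no
    pump backflow during diastole (minimum instantaneous flow above
    ``-backflow_tolerance`` l/min).  Both criteria improve monotonically
    with speed for a falling HQ characteristic, so the search bisects the
    grid; configurations where no speed satisfies both report
    ``feasible=False``.
    """
    from .network import run_to_steady_state  # local import: avoid cycle
    from .parameters import group_preset
    from .baroreflex import group_baroreflex
    from .analysis import beat_metrics

    params = group_preset(group)
    baro = group_baroreflex(group)
    evaluations = []

    def criteria(speed: float) -> Tuple[bool, float, float]:
        sol = run_to_steady_state(params, baro, rbp(inflow, speed, pump))
        m = beat_metrics(sol)
        ok = (m.lap < lap_limit) and (m.min_device_flow > -backflow_tolerance)
        evaluations.append((speed, m.lap, m.min_device_flow, ok))
        return ok, m.lap, m.min_device_flow

    lo = int(PUMP_SPEED_MIN // speed_grid)
    hi = int(PUMP_SPEED_MAX // speed_grid)
    ok_hi, lap_hi, qmin_hi = criteria(hi * speed_grid)
    if not ok_hi:
        return SpeedSelection(None, False, lap_hi, qmin_hi, tuple(evaluations))
    ok_lo, _, _ = criteria(lo * speed_grid)
    if ok_lo:
        best, lap_b, qmin_b = lo * speed_grid, None, None
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            ok, _, _ = criteria(mid * speed_grid)
            if ok:
                hi = mid
            else:
                lo = mid
        best = hi * speed_grid
    ok, lap_b, qmin_b = criteria(best)
    return SpeedSelection(best, True, lap_b, qmin_b, tuple(evaluations))
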