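"""Pressure-volume mechanics of the four heart chambers.

Each chamber is a time-varying-elastance element whose instantaneous
pressure interpolates between two bounding pressure-volume relations:

* ESPVR (end-systolic): a downward parabola with vertex ``(V_sys, P_sys)``
  crossing the volume axis at ``V_0`` (0 ml for the ventricles),

      P_es(V) = P_sys * [1 - ((V_sys - V) / (V_sys - V_0))**2]

* EDPVR (end-diastolic): the empirical power law of the Klotz single-beat
  family,

      P_ed(V) = alpha * V**beta

The activation fraction ``e(t)`` in [0, 1] rises during systole
(squared-sine ramp peaking after the systolic interval) and then decays
exponentially with the relaxation time constant ``tau_relax`` -- 54 ms for
the ventricles, reflecting the prolonged early relaxation typical of HFpEF.

The atria have no end-systolic relation of their own; they are modelled
as EDPVR chambers with a superimposed contraction ("atrial kick") of
peak elastance ``kick_elastance`` (mmHg/ml) timed ahead of ventricular
systole -- strong on the left, where it must push the final millilitres
of filling into the stiff ventricle, weak on the right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

#: Default systolic-interval scaling: systolic duration = 0.3 * sqrt(period).
SYSTOLIC_INTERVAL_FACTOR = 0.3

#: Atrial contraction starts this long (s) before ventricular activation onset.
ATRIAL_LEAD = 0.12


@dataclass
class ChamberParams:
    """Static pressure-volume parameters of one heart chamber.

    Parameters
    ----------
    alpha, beta
        EDPVR power-law coefficients (P = alpha * V**beta, mmHg / ml).
    v_sys, p_sys
        ESPVR parabola vertex (ml, mmHg).  ``None`` for atria, which have
        no end-systolic relation and instead use ``kick_elastance``.
    v_0
        Volume-axis crossing of the ESPVR (ml); 0 by assumption.
    tau_relax
        Exponential relaxation time constant of the activation tail (s).
    kick_elastance
        Peak active atrial elastance added above the EDPVR (mmHg/ml).
    activation_onset
        Activation onset relative to ventricular beat onset (s); negative
        values lead the ventricle (atrial kick).
    activation_duration
        Rise time to peak activation (s).  ``None`` means the ventricular
        default ``0.3 * sqrt(period)``.
    """

    alpha: float
    beta: float
    v_sys: Optional[float] = None
    p_sys: Optional[float] = None
    v_0: float = 0.0
    tau_relax: float = 0.054
    kick_elastance: float = 0.0
    activation_onset: float = 0.0
    activation_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        if not (self.beta > 1):
            raise ValueError("beta must be > 1")
        if not (self.tau_relax > 0):
            raise ValueError("tau_relax must be > 0")
        if self.v_0 < 0:
            raise ValueError("v_0 must be >= 0")
        if (self.v_sys is None) != (self.p_sys is None):
            raise ValueError("v_sys and p_sys must be given together")
        if self.v_sys is not None:
            if not (self.v_sys > self.v_0):
                raise ValueError("v_sys must exceed v_0")
            if not (self.p_sys > 0):
                raise ValueError("p_sys must be > 0")

    @property
    def is_atrium(self) -> bool:
        return self.v_sys is None


def _check_volume(volume: float) -> float:
    v = float(volume)
    if not math.isfinite(v) or v < 0:
        raise ValueError(f"volume must be finite and >= 0, got {volume!r}")
    return v


def espvr_pressure(volume: float, params: ChamberParams) -> float:
    """End-systolic pressure on the parabolic ESPVR (mmHg).

    Clipped at 0 beyond the far root ``2*v_sys - v_0`` so the relation
    itself never produces suction pressures (over-emptying is still
    observable through a pathologically low end-systolic volume).
    """
    v = _check_volume(volume)
    if params.is_atrium:
        raise ValueError("chamber has no ESPVR (atrium); use chamber_pressure")
    span = params.v_sys - params.v_0
    x = (params.v_sys - v) / span
    p = params.p_sys * (1.0 - x * x)
    return max(p, 0.0)


def edpvr_pressure(volume: float, params: ChamberParams) -> float:
    """End-diastolic pressure alpha * V**beta (mmHg); 0 at V = 0."""
    v = _check_volume(volume)
    if v == 0.0:
        return 0.0
    return params.alpha * v ** params.beta


def edpvr_volume(pressure: float, params: ChamberParams) -> float:
    """Inverse of :func:`edpvr_pressure` (ml)."""
    p = float(pressure)
    if p < 0 or not math.isfinite(p):
        raise ValueError("pressure must be finite and >= 0")
    if p == 0.0:
        return 0.0
    return (p / params.alpha) ** (1.0 / params.beta)


def activation(cycle_time: float, period: float, params: ChamberParams) -> float:
    """Activation fraction e(t) in [0, 1].

    Squared-sine rise from onset to peak over the activation duration,
    then exponential decay with ``tau_relax``; effectively zero in
    diastasis.  Periodic with the heart period.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    ct = float(cycle_time)
    if not (0.0 <= ct < period):
        raise ValueError("cycle_time must lie in [0, period)")
    tau = ct - params.activation_onset
    if tau < 0.0:
        tau += period
    duration = params.activation_duration
    if duration is None:
        duration = SYSTOLIC_INTERVAL_FACTOR * math.sqrt(period)
    if tau < duration:
        s = math.sin(0.5 * math.pi * tau / duration)
        return s * s
    return math.exp(-(tau - duration) / params.tau_relax)


def activation_rate(cycle_time: float, period: float, params: ChamberParams) -> float:
    """Time derivative de/dt of :func:`activation` (1/s)."""
    if period <= 0:
        raise ValueError("period must be > 0")
    tau = float(cycle_time) - params.activation_onset
    if tau < 0.0:
        tau += period
    duration = params.activation_duration
    if duration is None:
        duration = SYSTOLIC_INTERVAL_FACTOR * math.sqrt(period)
    if tau < duration:
        return 0.5 * math.pi / duration * math.sin(math.pi * tau / duration)
    return -math.exp(-(tau - duration) / params.tau_relax) / params.tau_relax


def chamber_pressure(volume: float, e: float, params: ChamberParams) -> float:
    """Instantaneous chamber pressure (mmHg) at activation fraction ``e``.

    Ventricles: P = e * ESPVR(V) + (1 - e) * EDPVR(V).
    Atria: P = EDPVR(V) + e * kick_elastance * V.
    """
    if not (0.0 <= e <= 1.0):
        raise ValueError("activation fraction e must lie in [0, 1]")
    if params.is_atrium:
        return edpvr_pressure(volume, params) + e * params.kick_elastance * _check_volume(volume)
    return e * espvr_pressure(volume, params) + (1.0 - e) * edpvr_pressure(volume, params)


def chamber_to_row(params: ChamberParams) -> np.ndarray:
    """Pack chamber parameters into the engine's per-chamber row layout."""
    return np.array(
        [
            params.v_sys if params.v_sys is not None else 0.0,
            params.p_sys if params.p_sys is not None else 0.0,
            params.alpha,
            params.beta,
            params.tau_relax,
            params.kick_elastance,
            1.0 if params.is_atrium else 0.0,
        ],
        dtype=np.float64,
    )
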