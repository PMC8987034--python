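"""Closed-loop assembly and integration to periodic steady state.

This module owns the state-vector plumbing around the compiled kernel in
:mod:`hfpefsim._engine`: building the initial condition from the mean
circulatory filling pressure, running the fixed-step integrator until the
beat-averaged hemodynamics are periodic, and wrapping the recorded final
beats in a :class:`PeriodicSolution` for analysis and CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine as eng
from .baroreflex import BaroreflexParams
from .chambers import edpvr_volume
from .devices import DeviceConfig, no_device
from .parameters import CirculationParams

#: Column names of the recorded time series, in engine order.
RECORD_COLUMNS = (
    "time", "cycle_time", "period",
    "v_lv", "v_rv", "v_la", "v_ra",
    "v_ao", "v_art_ub", "v_art_lb", "v_ven_ub", "v_ven_lb",
    "v_pa", "v_art_ll", "v_art_rl", "v_ven_ll", "v_ven_rl",
    "q_av", "q_pv", "q_mv", "q_tv",
    "q_pump", "map_filtered", "svr_scale", "volume_shift",
    "p_lv", "p_rv", "p_la", "p_ra",
    "p_ao", "p_art_ub", "p_art_lb", "p_ven_ub", "p_ven_lb",
    "p_pa", "p_art_ll", "p_art_rl", "p_ven_ll", "p_ven_rl",
    "q_ub", "q_lb", "q_ll", "q_rl", "q_sys",
    "q_iasd", "q_pump_alg", "q_copulse", "e_ventricle", "e_atrium",
    "v_copulse",
)

BEAT_COLUMNS = (
    "period", "map", "pap", "lap", "rap", "edv", "esv",
    "q_sys", "q_pump", "q_pump_min", "q_iasd", "volume_shift",
)

_VOLUME_COLUMNS = (
    "v_lv", "v_rv", "v_la", "v_ra",
    "v_ao", "v_art_ub", "v_art_lb", "v_ven_ub", "v_ven_lb",
    "v_pa", "v_art_ll", "v_art_rl", "v_ven_ll", "v_ven_rl",
)


@dataclass
class SolverSettings:
    """Fixed-step integrator and convergence controls.

    ``dt`` is the RK4 step (s); output is recorded every ``record_dt``.
    Convergence requires the beat-to-beat relative change of stroke
    volume, mean arterial pressure and mean left atrial pressure to stay
    below ``tolerance`` over ``window`` consecutive beats; ``min_beats``
    guards against declaring convergence while the slow autonomic
    effectors are still loading.
    """

    dt: float = 2.5e-4
    record_dt: float = 1e-3
    max_beats: int = 300
    min_beats: int = 25
    tolerance: float = 0.005
    window: int = 5
    record_beats: int = 5
    fixed_period: float = 0.8       # used when the baroreflex is disabled
    baroreflex_enabled: bool = True


@dataclass
class CirculationState:
    """Initial condition of the closed loop (packed engine layout)."""

    y: np.ndarray

    def total_blood_volume(self) -> float:
        return float(np.sum(self.y[eng.IV_LV:eng.IV_VEN_RL + 1]))


@dataclass
class PeriodicSolution:
    """Converged final beats of one run at 1 ms resolution."""

    data: pd.DataFrame
    beats: pd.DataFrame
    converged: bool
    n_beats_run: int
    params: CirculationParams
    baro: BaroreflexParams
    device: DeviceConfig
    settings: SolverSettings = field(default_factory=SolverSettings)

    def beat_starts(self) -> np.ndarray:
        """Indices where a new beat begins in the recorded window."""
        ct = self.data["cycle_time"].to_numpy()
        starts = np.flatnonzero(np.diff(ct) < 0) + 1
        return np.concatenate(([0], starts))

    def total_blood_volume(self) -> pd.Series:
        """Conserved blood volume: circulation + device chamber - reflex
        volume recruited from the unstressed reserve."""
        total = self.data[list(_VOLUME_COLUMNS)].sum(axis=1)
        return total + self.data["v_copulse"] - self.data["volume_shift"]

    def to_csv(self, path, provenance: str = "") -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            self.data.to_csv(fh, index=False)


def initialize_state(
    params: CirculationParams,
    baro: Optional[BaroreflexParams] = None,
) -> CirculationState:
    """Uniform-pressure start: every node at MCFP, zero flow everywhere.

    Vascular stressed volumes are ``C * MCFP``; chambers start on their
    EDPVR at the same pressure.  With activation frozen at zero and all
    valves closed this is a flow equilibrium of the network.
    """
    y = np.zeros(eng.NSTATE, dtype=np.float64)
    p = params.mcfp
    y[eng.IV_LV] = edpvr_volume(p, params.lv)
    y[eng.IV_RV] = edpvr_volume(p, params.rv)
    y[eng.IV_LA] = edpvr_volume(p, params.la)
    y[eng.IV_RA] = edpvr_volume(p, params.ra)
    for idx, c in (
        (eng.IV_AO, params.c_ao),
        (eng.IV_ART_UB, params.cart_ub), (eng.IV_ART_LB, params.cart_lb),
        (eng.IV_VEN_UB, params.cven_ub), (eng.IV_VEN_LB, params.cven_lb),
        (eng.IV_PA, params.c_pa),
        (eng.IV_ART_LL, params.cart_ll), (eng.IV_ART_RL, params.cart_rl),
        (eng.IV_VEN_LL, params.cven_ll), (eng.IV_VEN_RL, params.cven_rl),
    ):
        y[idx] = c * p
    y[eng.IB_SVR] = 1.0
    y[eng.IB_VOL] = 0.0
    # start the afferent filter at the effector-neutral pressure so the
    # reflex ramps in smoothly from its resting operating point
    y[eng.IB_MAPF] = (baro.map_setpoint - baro.dp0) if baro is not None else p
    return CirculationState(y=y)


def run_to_steady_state(
    params: CirculationParams,
    baro: BaroreflexParams,
    device: Optional[DeviceConfig] = None,
    settings: Optional[SolverSettings] = None,
    initial: Optional[CirculationState] = None,
) -> PeriodicSolution:
    """Integrate the closed loop until beat metrics are periodic.

    Deterministic: identical inputs reproduce identical outputs bit for
    bit.  Non-convergence within the beat budget is flagged on the
    returned solution, never silent.
    """
    device = device or no_device()
    settings = settings or SolverSettings()
    state = initial or initialize_state(params, baro)

    rec_stride = max(int(round(settings.record_dt / settings.dt)), 1)
    rec, n_rec, beatm, n_beats, converged = eng.simulate(
        state.y,
        params.chamber_matrix(),
        params.vascular_vector(),
        baro.vector(settings.baroreflex_enabled, settings.fixed_period),
        device.vector(),
        settings.dt,
        rec_stride,
        settings.max_beats,
        settings.min_beats,
        settings.tolerance,
        settings.window,
        settings.record_beats,
    )
    data = pd.DataFrame(rec, columns=list(RECORD_COLUMNS))
    beats = pd.DataFrame(beatm, columns=list(BEAT_COLUMNS))
    return PeriodicSolution(
        data=data, beats=beats, converged=bool(converged),
        n_beats_run=int(n_beats), params=params, baro=baro,
        device=device, settings=settings,
    )


def valve_flow(p_upstream: float, p_downstream: float, r: float,
               l: float = 0.0, q: float = 0.0) -> float:
    """Ideal-diode valve law (reference implementation).

    With no inertance the element is algebraic: forward flow ``dp / r``
    when the valve is open, zero when closed.  With inertance the flow is
    a state and the returned value is its derivative ``dq/dt``.
    """
    if r < 0:
        raise ValueError("valve resistance must be >= 0")
    dp = p_upstream - p_downstream
    if l == 0.0:
        return dp / r if dp > 0.0 else 0.0
    q = max(q, 0.0)
    if dp > 0.0 or q > 0.0:
        return (dp - r * q) / l
    return 0.0
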