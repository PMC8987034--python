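"""Vascular network parameters and the two HFpEF phenotype presets.

The closed loop consists of the four elastance chambers plus a systemic
and a pulmonary circulation, each modelled as 3-element arterial and
2-element venous Windkessel compartments.  The systemic side splits into
parallel upper-body and lower-body branches between the ascending aorta
and the right atrium; the pulmonary side splits into left-lung and
right-lung branches between the pulmonary artery and the left atrium.

Units follow the model convention throughout: pressures in mmHg, volumes
in ml, flows in ml/s, resistances in mmHg*s/ml, compliances in ml/mmHg,
inertances in mmHg*s^2/ml.

Two phenotype presets are provided:

* Group 1 -- low cardiac output (4.4 l/min) with elevated transpulmonary
  gradient (10 mmHg); restrictive/infiltrative phenotype.
* Group 2 -- elevated cardiac output (6.3 l/min) with normal
  transpulmonary gradient (4 mmHg); comorbidity-driven phenotype.

The right-ventricular EDPVR coefficients are not part of the published
parameter set; the values below were calibrated so that right-sided
filling pressures, pulmonary pressures and output are mutually consistent
with the phenotype targets (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

from .chambers import ChamberParams, chamber_to_row, ATRIAL_LEAD

# ---------------------------------------------------------------------------
# engine packing indices for the vascular parameter vector
# ---------------------------------------------------------------------------
R_AO, C_AO, L_AO, L_PA = 0, 1, 2, 3
RC_UB, RC_LB, CART_UB, CART_LB, RART_UB, RART_LB = 4, 5, 6, 7, 8, 9
CVEN_UB, CVEN_LB, RVEN_UB, RVEN_LB = 10, 11, 12, 13
R_PA, C_PA, RC_LL, RC_RL, CART_LL, CART_RL = 14, 15, 16, 17, 18, 19
RART_LL, RART_RL, CVEN_LL, CVEN_RL, RVEN_LL, RVEN_RL = 20, 21, 22, 23, 24, 25
LIN_RV, LIN_LV, RIN_RV, RIN_LV = 26, 27, 28, 29
MCFP_IDX, CTOT_IDX, ATR_LEAD_IDX = 30, 31, 32
NVS = 33

_VS_FIELDS = (
    "r_ao", "c_ao", "l_ao", "l_pa",
    "rc_ub", "rc_lb", "cart_ub", "cart_lb", "rart_ub", "rart_lb",
    "cven_ub", "cven_lb", "rven_ub", "rven_lb",
    "r_pa", "c_pa", "rc_ll", "rc_rl", "cart_ll", "cart_rl",
    "rart_ll", "rart_rl", "cven_ll", "cven_rl", "rven_ll", "rven_rl",
    "lin_rv", "lin_lv", "rin_rv", "rin_lv",
    "mcfp", "total_compliance",
)


@dataclass
class CirculationParams:
    """All vascular elements of the closed loop plus the four chambers."""

    # aortic root / pulmonary trunk
    r_ao: float
    c_ao: float
    l_ao: float
    l_pa: float
    # systemic branches (upper body / lower body)
    rc_ub: float
    rc_lb: float
    cart_ub: float
    cart_lb: float
    rart_ub: float
    rart_lb: float
    cven_ub: float
    cven_lb: float
    rven_ub: float
    rven_lb: float
    # pulmonary trunk node and lung branches (left / right lung)
    r_pa: float
    c_pa: float
    rc_ll: float
    rc_rl: float
    cart_ll: float
    cart_rl: float
    rart_ll: float
    rart_rl: float
    cven_ll: float
    cven_rl: float
    rven_ll: float
    rven_rl: float
    # ventricular inflow tracts
    lin_rv: float
    lin_lv: float
    rin_rv: float
    rin_lv: float
    # filling status
    mcfp: float
    total_compliance: float = 120.0
    # chambers
    lv: ChamberParams = field(default=None)  # type: ignore[assignment]
    rv: ChamberParams = field(default=None)  # type: ignore[assignment]
    la: ChamberParams = field(default=None)  # type: ignore[assignment]
    ra: ChamberParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in _VS_FIELDS:
            value = getattr(self, name)
            if value is None or value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not (self.mcfp > 0):
            raise ValueError("mcfp must be > 0")
        for name in ("lv", "rv", "la", "ra"):
            if getattr(self, name) is None:
                raise ValueError(f"chamber parameters '{name}' are required")

    # -- engine packing ----------------------------------------------------
    def vascular_vector(self) -> np.ndarray:
        vec = np.zeros(NVS, dtype=np.float64)
        for i, name in enumerate(_VS_FIELDS):
            vec[i] = getattr(self, name)
        vec[ATR_LEAD_IDX] = ATRIAL_LEAD
        return vec

    def chamber_matrix(self) -> np.ndarray:
        return np.stack(
            [chamber_to_row(c) for c in (self.lv, self.rv, self.la, self.ra)]
        )

    def compliance_sum(self) -> float:
        """Sum of all vascular compliances (ml/mmHg)."""
        return (
            self.c_ao + self.cart_ub + self.cart_lb + self.cven_ub + self.cven_lb
            + self.c_pa + self.cart_ll + self.cart_rl + self.cven_ll + self.cven_rl
        )

    def total_svr(self) -> float:
        """Series-parallel systemic resistance from aorta to right atrium."""
        rc = _par(self.rc_ub, self.rc_lb)
        rart = _par(self.rart_ub, self.rart_lb)
        rven = _par(self.rven_ub, self.rven_lb)
        return self.r_ao + rc + rart + rven

    def total_pvr(self) -> float:
        """Series-parallel pulmonary resistance from PA trunk to left atrium."""
        rc = _par(self.rc_ll, self.rc_rl)
        rart = _par(self.rart_ll, self.rart_rl)
        rven = _par(self.rven_ll, self.rven_rl)
        return self.r_pa + rc + rart + rven

    def copy(self) -> "CirculationParams":
        return replace(self)


def _par(r1: float, r2: float) -> float:
    return r1 * r2 / (r1 + r2)


# ---------------------------------------------------------------------------
# phenotype presets
# ---------------------------------------------------------------------------

#: Atrial EDPVR shared by LA and RA (enlarged HFpEF atria: ~90 ml at 15 mmHg).
ATRIAL_ALPHA = 2.9417e-5
ATRIAL_BETA = 2.9139

#: Atrial contraction: peak active elastance above the EDPVR (mmHg/ml).
#: The left atrium contracts forcefully (it must push the final ~10 ml of
#: filling into a stiff ventricle at end diastole, which is what keeps the
#: mean LAP below the ventricular end-diastolic pressure); the right
#: atrial kick against the compliant RV is weak.
LA_KICK_ELASTANCE = 1.0
RA_KICK_ELASTANCE = 0.04
ATRIAL_ACTIVATION_DURATION = 0.06  # rise time to peak (s); short, sharp kick
ATRIAL_TAU_RELAX = 0.03

#: Ventricular early-relaxation time constant (s), elevated in HFpEF.
VENTRICULAR_TAU_RELAX = 0.054


def _atrium(kick: float) -> ChamberParams:
    return ChamberParams(
        alpha=ATRIAL_ALPHA,
        beta=ATRIAL_BETA,
        tau_relax=ATRIAL_TAU_RELAX,
        kick_elastance=kick,
        activation_onset=-ATRIAL_LEAD,
        activation_duration=ATRIAL_ACTIVATION_DURATION,
    )


_GROUP1 = dict(
    r_ao=0.0075, c_ao=0.1619, l_ao=5.5669e-5, l_pa=5.5669e-5,
    rc_ub=0.0384, rc_lb=0.0154, cart_ub=0.1619, cart_lb=0.4857,
    rart_ub=3.813, rart_lb=1.5205,
    cven_ub=25.2967, cven_lb=75.8929, rven_ub=0.245, rven_lb=0.098,
    r_pa=0.0075, c_pa=0.4909,
    rc_ll=0.0026, rc_rl=0.0026, cart_ll=0.9818, cart_rl=0.9818,
    rart_ll=0.2528, rart_rl=0.2528,
    cven_ll=7.7727, cven_rl=7.7727, rven_ll=0.0192, rven_rl=0.0192,
    lin_rv=2.78344e-5, lin_lv=2.78344e-5, rin_rv=0.00125, rin_lv=0.00125,
    mcfp=12.7,
)

_GROUP2 = dict(
    r_ao=0.0075, c_ao=0.1619, l_ao=5.5669e-5, l_pa=5.5669e-5,
    rc_ub=0.0308, rc_lb=0.0123, cart_ub=0.1619, cart_lb=0.4857,
    rart_ub=3.0453, rart_lb=1.2181,
    cven_ub=25.2967, cven_lb=75.8929, rven_ub=0.245, rven_lb=0.098,
    r_pa=0.0075, c_pa=0.4909,
    rc_ll=0.0011, rc_rl=0.0011, cart_ll=0.9818, cart_rl=0.9818,
    rart_ll=0.1059, rart_rl=0.1059,
    cven_ll=7.7727, cven_rl=7.7727, rven_ll=0.0081, rven_rl=0.0081,
    lin_rv=2.78344e-5, lin_lv=2.78344e-5, rin_rv=0.00125, rin_lv=0.00125,
    mcfp=14.3,
)

#: Calibrated right-ventricular EDPVR coefficients (not in the published
#: parameter set; see module docstring).
_RV_EDPVR = {1: (3.3e-6, 3.0), 2: (3.9e-6, 3.0)}

_LV_PARAMS = {1: dict(v_sys=140.0, p_sys=220.0, alpha=5.5742e-6, beta=3.3186),
              2: dict(v_sys=150.0, p_sys=235.0, alpha=9.1293e-7, beta=3.4085)}
_RV_VERTEX = {1: (190.0, 60.0), 2: (180.0, 95.0)}


def group_preset(group: int) -> CirculationParams:
    """Full calibrated parameter set for phenotype group 1 or 2 at rest."""
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    vasc = dict(_GROUP1 if group == 1 else _GROUP2)
    lvp = _LV_PARAMS[group]
    rv_vsys, rv_psys = _RV_VERTEX[group]
    rv_alpha, rv_beta = _RV_EDPVR[group]
    return CirculationParams(
        **vasc,
        lv=ChamberParams(
            alpha=lvp["alpha"], beta=lvp["beta"], v_sys=lvp["v_sys"],
            p_sys=lvp["p_sys"], tau_relax=VENTRICULAR_TAU_RELAX,
        ),
        rv=ChamberParams(
            alpha=rv_alpha, beta=rv_beta, v_sys=rv_vsys, p_sys=rv_psys,
            tau_relax=VENTRICULAR_TAU_RELAX,
        ),
        la=_atrium(LA_KICK_ELASTANCE),
        ra=_atrium(RA_KICK_ELASTANCE),
    )


#: Rest/exercise hemodynamic reference panels for both groups: the
#: literature targets (central value plus dispersion) and the values the
#: calibrated closed-loop model is expected to reproduce.
GROUPS = (1, 2)
CONDITIONS = ("rest", "exercise")
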