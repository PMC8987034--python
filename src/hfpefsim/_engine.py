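"""Compiled fixed-step integrator for the closed-loop circulation.

The state vector (length 22) carries chamber volumes, stressed volumes of
the ten vascular compliance nodes, the four valve/inertance flows, the
rotary-pump flow and three slow autonomic states (filtered arterial
pressure, resistance scale, stressed-volume shift).

The loop is advanced with classical RK4 at a fixed 0.25 ms step -- well
below the fastest network time constants (~2 ms) -- which makes runs
bit-reproducible.  Valves are ideal diodes realised by integrating the
series R-L branch while forward-biased and clamping the flow state at
zero otherwise, so closed valves carry exactly zero flow (no leak, no
regurgitation).  The heart period is re-evaluated from the baroreflex
sigmoid at each beat boundary.

Beat-averaged metrics are accumulated on the fly; once stroke volume,
arterial pressure and left atrial pressure are all beat-to-beat stable
(relative change below the convergence tolerance over a trailing window)
the integrator records a final stretch of beats at 1 ms resolution and
stops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# state vector layout
# ---------------------------------------------------------------------------
IV_LV, IV_RV, IV_LA, IV_RA = 0, 1, 2, 3
IV_AO, IV_ART_UB, IV_ART_LB, IV_VEN_UB, IV_VEN_LB = 4, 5, 6, 7, 8
IV_PA, IV_ART_LL, IV_ART_RL, IV_VEN_LL, IV_VEN_RL = 9, 10, 11, 12, 13
IQ_AV, IQ_PV, IQ_MV, IQ_TV = 14, 15, 16, 17
IQ_PUMP, IB_MAPF, IB_SVR, IB_VOL = 18, 19, 20, 21
NSTATE = 22

# chamber matrix columns
CH_VSYS, CH_PSYS, CH_ALPHA, CH_BETA, CH_TAU, CH_KICK, CH_ISATR = 0, 1, 2, 3, 4, 5, 6

# vascular vector indices (mirror of parameters.py)
R_AO, C_AO, L_AO, L_PA = 0, 1, 2, 3
RC_UB, RC_LB, CART_UB, CART_LB, RART_UB, RART_LB = 4, 5, 6, 7, 8, 9
CVEN_UB, CVEN_LB, RVEN_UB, RVEN_LB = 10, 11, 12, 13
R_PA, C_PA, RC_LL, RC_RL, CART_LL, CART_RL = 14, 15, 16, 17, 18, 19
RART_LL, RART_RL, CVEN_LL, CVEN_RL, RVEN_LL, RVEN_RL = 20, 21, 22, 23, 24, 25
LIN_RV, LIN_LV, RIN_RV, RIN_LV = 26, 27, 28, 29
MCFP_IDX, CTOT_IDX, ATR_LEAD_IDX = 30, 31, 32

# baroreflex vector indices (mirror of baroreflex.py)
BR_TMIN, BR_TMAX, BR_GHR, BR_SETPT, BR_SVR_GAIN, BR_VOL_GAIN = 0, 1, 2, 3, 4, 5
BR_DP0, BR_VOL_MAX, BR_TAU_EFF, BR_TAU_MAP, BR_ON, BR_FIXED_T = 6, 7, 8, 9, 10, 11
BR_PULM_FRAC, BR_SVR_MAX = 12, 13

# device vector indices (mirror of devices.py)
DV_KIND, DV_IASD_R, DV_SPEED, DV_PA, DV_PB, DV_PC = 0, 1, 2, 3, 4, 5
DV_LPUMP, DV_STROKE, DV_COP_RC, DV_COP_LC = 6, 7, 8, 9

# auxiliary (algebraic) output layout
A_P_LV, A_P_RV, A_P_LA, A_P_RA = 0, 1, 2, 3
A_P_AO, A_P_ART_UB, A_P_ART_LB, A_P_VEN_UB, A_P_VEN_LB = 4, 5, 6, 7, 8
A_P_PA, A_P_ART_LL, A_P_ART_RL, A_P_VEN_LL, A_P_VEN_RL = 9, 10, 11, 12, 13
A_Q_UB, A_Q_LB, A_Q_LL, A_Q_RL, A_Q_SYS = 14, 15, 16, 17, 18
A_Q_IASD, A_Q_PUMP, A_Q_COP, A_E_V, A_E_A, A_VCOP = 19, 20, 21, 22, 23, 24
NAUX = 25

# beat-metric row layout
BM_PERIOD, BM_MAP, BM_PAP, BM_LAP, BM_RAP = 0, 1, 2, 3, 4
BM_EDV, BM_ESV, BM_CO, BM_QPUMP, BM_QPUMP_MIN, BM_QIASD, BM_VSHIFT = 5, 6, 7, 8, 9, 10, 11
NBM = 12

_SYS_FACTOR = 0.3        # systolic interval (rise + plateau) = 0.3 * sqrt(period)
_SYS_PLATEAU = 0.07      # peak-activation plateau within the systolic interval (s)
_ATR_RISE = 0.10         # atrial activation rise time (s)
_SUCTION_VOL = 3.0       # ml; below this the pump inflow is braked
_COP_DELAY = 0.07        # co-pulsation drive delay behind native systole (s)


@njit(cache=True)
def _wave(tau, rise, plateau, tau_relax):
    if tau < rise:
        s = np.sin(0.5 * np.pi * tau / rise)
        return s * s
    if tau < rise + plateau:
        return 1.0
    return np.exp(-(tau - rise - plateau) / tau_relax)


@njit(cache=True)
def _wave_rate(tau, rise, plateau, tau_relax):
    if tau < rise:
        return 0.5 * np.pi / rise * np.sin(np.pi * tau / rise)
    if tau < rise + plateau:
        return 0.0
    return -np.exp(-(tau - rise - plateau) / tau_relax) / tau_relax


@njit(cache=True)
def _espvr(v, vsys, psys):
    x = (vsys - v) / vsys
    p = psys * (1.0 - x * x)
    return p if p > 0.0 else 0.0


@njit(cache=True)
def _edpvr(v, alpha, beta):
    if v <= 0.0:
        return 0.0
    return alpha * v ** beta


@njit(cache=True)
def _period_from_map(mapf, br):
    x = -(br[BR_SETPT] - mapf) * br[BR_GHR]
    if x > 50.0:
        w = 1.0
    elif x < -50.0:
        w = 0.0
    else:
        e = np.exp(x)
        w = e / (1.0 + e)
    return br[BR_TMIN] + (br[BR_TMAX] - br[BR_TMIN]) * w


@njit(cache=True)
def _rhs(ct, period, y, ch, vs, br, dv, dy, aux):
    """Time derivative of the state; algebraic quantities written to aux."""
    # --- activations ------------------------------------------------------
    dur_v = _SYS_FACTOR * np.sqrt(period)
    rise_v = dur_v - _SYS_PLATEAU
    e_lv = _wave(ct, rise_v, _SYS_PLATEAU, ch[0, CH_TAU])
    e_rv = _wave(ct, rise_v, _SYS_PLATEAU, ch[1, CH_TAU])
    ta = ct - (period - vs[ATR_LEAD_IDX])
    if ta < 0.0:
        ta += period
    e_la = _wave(ta, _ATR_RISE, 0.0, ch[2, CH_TAU])
    e_ra = _wave(ta, _ATR_RISE, 0.0, ch[3, CH_TAU])

    # --- chamber pressures ------------------------------------------------
    v_lv, v_rv, v_la, v_ra = y[IV_LV], y[IV_RV], y[IV_LA], y[IV_RA]
    p_lv = e_lv * _espvr(v_lv, ch[0, CH_VSYS], ch[0, CH_PSYS]) \
        + (1.0 - e_lv) * _edpvr(v_lv, ch[0, CH_ALPHA], ch[0, CH_BETA])
    p_rv = e_rv * _espvr(v_rv, ch[1, CH_VSYS], ch[1, CH_PSYS]) \
        + (1.0 - e_rv) * _edpvr(v_rv, ch[1, CH_ALPHA], ch[1, CH_BETA])
    p_la = _edpvr(v_la, ch[2, CH_ALPHA], ch[2, CH_BETA]) + e_la * ch[2, CH_KICK] * v_la
    p_ra = _edpvr(v_ra, ch[3, CH_ALPHA], ch[3, CH_BETA]) + e_ra * ch[3, CH_KICK] * v_ra

    # --- vascular node pressures -----------------------------------------
    p_ao = y[IV_AO] / vs[C_AO]
    p_art_ub = y[IV_ART_UB] / vs[CART_UB]
    p_art_lb = y[IV_ART_LB] / vs[CART_LB]
    p_ven_ub = y[IV_VEN_UB] / vs[CVEN_UB]
    p_ven_lb = y[IV_VEN_LB] / vs[CVEN_LB]
    p_pa = y[IV_PA] / vs[C_PA]
    p_art_ll = y[IV_ART_LL] / vs[CART_LL]
    p_art_rl = y[IV_ART_RL] / vs[CART_RL]
    p_ven_ll = y[IV_VEN_LL] / vs[CVEN_LL]
    p_ven_rl = y[IV_VEN_RL] / vs[CVEN_RL]

    # --- baroreflex -------------------------------------------------------
    # y[IB_MAPF] holds the mean arterial pressure of the last completed
    # beat (updated at beat boundaries by the integrator); using the beat
    # mean rather than a filtered instantaneous pressure keeps the
    # afferent signal free of pulse-phase bias.
    baro_on = br[BR_ON] > 0.5
    svr_scale = y[IB_SVR] if baro_on else 1.0
    d_mapf = 0.0
    d_svr = 0.0
    d_vol = 0.0
    if baro_on:
        dpe = (br[BR_SETPT] - y[IB_MAPF]) - br[BR_DP0]
        s_tgt = 1.0 + br[BR_SVR_GAIN] * dpe
        if s_tgt < 0.3:
            s_tgt = 0.3
        elif s_tgt > br[BR_SVR_MAX]:
            s_tgt = br[BR_SVR_MAX]
        d_svr = (s_tgt - y[IB_SVR]) / br[BR_TAU_EFF]
        v_tgt = br[BR_VOL_GAIN] * dpe
        if v_tgt > br[BR_VOL_MAX]:
            v_tgt = br[BR_VOL_MAX]
        elif v_tgt < -br[BR_VOL_MAX]:
            v_tgt = -br[BR_VOL_MAX]
        d_vol = (v_tgt - y[IB_VOL]) / br[BR_TAU_EFF]

    # --- systemic branch flows (resistive) --------------------------------
    q_ub = (p_ao - p_art_ub) / vs[RC_UB]
    q_lb = (p_ao - p_art_lb) / vs[RC_LB]
    q_art_ub = (p_art_ub - p_ven_ub) / (vs[RART_UB] * svr_scale)
    q_art_lb = (p_art_lb - p_ven_lb) / (vs[RART_LB] * svr_scale)
    q_ven_ub = (p_ven_ub - p_ra) / vs[RVEN_UB]
    q_ven_lb = (p_ven_lb - p_ra) / vs[RVEN_LB]

    # --- pulmonary branch flows ------------------------------------------
    q_ll = (p_pa - p_art_ll) / vs[RC_LL]
    q_rl = (p_pa - p_art_rl) / vs[RC_RL]
    q_art_ll = (p_art_ll - p_ven_ll) / vs[RART_LL]
    q_art_rl = (p_art_rl - p_ven_rl) / vs[RART_RL]
    q_ven_ll = (p_ven_ll - p_la) / vs[RVEN_LL]
    q_ven_rl = (p_ven_rl - p_la) / vs[RVEN_RL]

    # --- valves (ideal diodes with series R-L) ---------------------------
    q_av = y[IQ_AV]
    if q_av < 0.0:
        q_av = 0.0
    dp = p_lv - p_ao
    dq_av = (dp - vs[R_AO] * q_av) / vs[L_AO] if (dp > 0.0 or q_av > 0.0) else 0.0

    q_pv = y[IQ_PV]
    if q_pv < 0.0:
        q_pv = 0.0
    dp = p_rv - p_pa
    dq_pv = (dp - vs[R_PA] * q_pv) / vs[L_PA] if (dp > 0.0 or q_pv > 0.0) else 0.0

    q_mv = y[IQ_MV]
    if q_mv < 0.0:
        q_mv = 0.0
    dp = p_la - p_lv
    dq_mv = (dp - vs[RIN_LV] * q_mv) / vs[LIN_LV] if (dp > 0.0 or q_mv > 0.0) else 0.0

    q_tv = y[IQ_TV]
    if q_tv < 0.0:
        q_tv = 0.0
    dp = p_ra - p_rv
    dq_tv = (dp - vs[RIN_RV] * q_tv) / vs[LIN_RV] if (dp > 0.0 or q_tv > 0.0) else 0.0

    # --- devices ----------------------------------------------------------
    kind = int(dv[DV_KIND])
    q_iasd = 0.0
    q_pump = 0.0
    dq_pump = 0.0
    q_cop = 0.0
    vcop = 0.0
    if kind == 1:                                   # interatrial shunt
        q_iasd = (p_la - p_ra) / dv[DV_IASD_R]
    elif kind == 2 or kind == 3:                    # rotary pump (LV / LA inflow)
        q_pump = y[IQ_PUMP]
        qlpm = 0.06 * q_pump
        head = dv[DV_PA] * dv[DV_SPEED] * dv[DV_SPEED] \
            - dv[DV_PB] * qlpm * abs(qlpm) - dv[DV_PC] * qlpm
        p_in = p_lv if kind == 2 else p_la
        dq_pump = (p_in + head - p_ao) / dv[DV_LPUMP]
        v_src = v_lv if kind == 2 else v_la
        if v_src < _SUCTION_VOL and q_pump > 0.0:   # inflow collapse guard
            dq_pump -= q_pump * (_SUCTION_VOL - v_src) * 100.0
    elif kind == 4:                                 # co-pulsating chamber
        # The chamber empties into the LV with the systolic activation rise
        # (lagging it by the drive delay, so the tail of the ejected volume
        # arrives around aortic valve closure) and refills from the LV
        # slowly over the whole diastolic window, so it never sucks the
        # relaxing ventricle dry.
        tc = ct - _COP_DELAY
        if tc < 0.0:
            tc += period
        t0 = rise_v + _SYS_PLATEAU
        if tc < rise_v:
            sw = np.sin(0.5 * np.pi * tc / rise_v)
            w = sw * sw
            dw = 0.5 * np.pi / rise_v * np.sin(np.pi * tc / rise_v)
        elif tc < t0:
            w = 1.0
            dw = 0.0
        else:
            x = (tc - t0) / (period - t0)
            cw = np.cos(0.5 * np.pi * x)
            w = cw * cw
            dw = -0.5 * np.pi / (period - t0) * np.sin(np.pi * x)
        q_cop = dv[DV_STROKE] * dw                  # into the LV
        vcop = dv[DV_STROKE] * (1.0 - w)

    # --- node balances ----------------------------------------------------
    dy[IV_LV] = q_mv - q_av + q_cop - (q_pump if kind == 2 else 0.0)
    dy[IV_RV] = q_tv - q_pv
    dy[IV_LA] = q_ven_ll + q_ven_rl - q_mv - q_iasd - (q_pump if kind == 3 else 0.0)
    dy[IV_RA] = q_ven_ub + q_ven_lb - q_tv + q_iasd

    dy[IV_AO] = q_av - q_ub - q_lb + (q_pump if (kind == 2 or kind == 3) else 0.0)
    dy[IV_ART_UB] = q_ub - q_art_ub
    dy[IV_ART_LB] = q_lb - q_art_lb
    d_vol_sys = d_vol * (1.0 - br[BR_PULM_FRAC])
    d_vol_pul = d_vol * br[BR_PULM_FRAC]
    frac_ub = vs[CVEN_UB] / (vs[CVEN_UB] + vs[CVEN_LB])
    dy[IV_VEN_UB] = q_art_ub - q_ven_ub + d_vol_sys * frac_ub
    dy[IV_VEN_LB] = q_art_lb - q_ven_lb + d_vol_sys * (1.0 - frac_ub)

    dy[IV_PA] = q_pv - q_ll - q_rl
    dy[IV_ART_LL] = q_ll - q_art_ll
    dy[IV_ART_RL] = q_rl - q_art_rl
    dy[IV_VEN_LL] = q_art_ll - q_ven_ll + 0.5 * d_vol_pul
    dy[IV_VEN_RL] = q_art_rl - q_ven_rl + 0.5 * d_vol_pul

    dy[IQ_AV] = dq_av
    dy[IQ_PV] = dq_pv
    dy[IQ_MV] = dq_mv
    dy[IQ_TV] = dq_tv
    dy[IQ_PUMP] = dq_pump
    dy[IB_MAPF] = d_mapf
    dy[IB_SVR] = d_svr
    dy[IB_VOL] = d_vol

    # --- auxiliaries ------------------------------------------------------
    aux[A_P_LV] = p_lv
    aux[A_P_RV] = p_rv
    aux[A_P_LA] = p_la
    aux[A_P_RA] = p_ra
    aux[A_P_AO] = p_ao
    aux[A_P_ART_UB] = p_art_ub
    aux[A_P_ART_LB] = p_art_lb
    aux[A_P_VEN_UB] = p_ven_ub
    aux[A_P_VEN_LB] = p_ven_lb
    aux[A_P_PA] = p_pa
    aux[A_P_ART_LL] = p_art_ll
    aux[A_P_ART_RL] = p_art_rl
    aux[A_P_VEN_LL] = p_ven_ll
    aux[A_P_VEN_RL] = p_ven_rl
    aux[A_Q_UB] = q_ub
    aux[A_Q_LB] = q_lb
    aux[A_Q_LL] = q_ll
    aux[A_Q_RL] = q_rl
    aux[A_Q_SYS] = q_ub + q_lb
    aux[A_Q_IASD] = q_iasd
    aux[A_Q_PUMP] = q_pump
    aux[A_Q_COP] = q_cop
    aux[A_E_V] = e_lv
    aux[A_E_A] = e_la
    aux[A_VCOP] = vcop


@njit(cache=True)
def simulate(y0, ch, vs, br, dv, dt, rec_stride, max_beats, min_beats,
             conv_tol, conv_window, n_rec_beats):
    """Integrate to periodic steady state, then record final beats.

    Returns ``(rec, n_rec, beat_metrics, n_beats, converged)`` where
    ``rec`` rows are ``[t, cycle_time, period] + state + aux`` sampled
    every ``rec_stride`` steps during the final ``n_rec_beats`` beats.
    """
    y = y0.copy()
    dy = np.zeros(NSTATE)
    k1 = np.zeros(NSTATE)
    k2 = np.zeros(NSTATE)
    k3 = np.zeros(NSTATE)
    k4 = np.zeros(NSTATE)
    yt = np.zeros(NSTATE)
    aux = np.zeros(NAUX)
    aux_t = np.zeros(NAUX)

    baro_on = br[BR_ON] > 0.5
    period = _period_from_map(y[IB_MAPF], br) if baro_on else br[BR_FIXED_T]

    ncols = 3 + NSTATE + NAUX
    nrecmax = int((n_rec_beats * 1.6) / (dt * rec_stride)) + 64
    rec = np.zeros((nrecmax, ncols))
    beatm = np.zeros((max_beats, NBM))
    sv_hist = np.zeros(max_beats)
    map_hist = np.zeros(max_beats)
    lap_hist = np.zeros(max_beats)

    t = 0.0
    ct = 0.0
    beat = 0
    step_in_beat = 0
    n_rec = 0
    recording = False
    rec_beats_left = 0
    converged = False

    # per-beat accumulators
    acc_time = 0.0
    acc_map = 0.0
    acc_pap = 0.0
    acc_lap = 0.0
    acc_rap = 0.0
    acc_qsys = 0.0
    acc_qpump = 0.0
    acc_qiasd = 0.0
    vmax = -1.0e30
    vmin = 1.0e30
    qpump_min = 1.0e30

    while beat < max_beats:
        _rhs(ct, period, y, ch, vs, br, dv, k1, aux)

        # accumulate beat statistics at the pre-step state
        acc_time += dt
        acc_map += aux[A_P_AO] * dt
        acc_pap += aux[A_P_PA] * dt
        acc_lap += aux[A_P_LA] * dt
        acc_rap += aux[A_P_RA] * dt
        acc_qsys += aux[A_Q_SYS] * dt
        acc_qpump += aux[A_Q_PUMP] * dt
        acc_qiasd += aux[A_Q_IASD] * dt
        if y[IV_LV] > vmax:
            vmax = y[IV_LV]
        if y[IV_LV] < vmin:
            vmin = y[IV_LV]
        if aux[A_Q_PUMP] < qpump_min:
            qpump_min = aux[A_Q_PUMP]

        if recording and (step_in_beat % rec_stride == 0) and n_rec < nrecmax:
            rec[n_rec, 0] = t
            rec[n_rec, 1] = ct
            rec[n_rec, 2] = period
            for i in range(NSTATE):
                rec[n_rec, 3 + i] = y[i]
            for i in range(NAUX):
                rec[n_rec, 3 + NSTATE + i] = aux[i]
            n_rec += 1

        # RK4 step
        for i in range(NSTATE):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(ct + 0.5 * dt, period, yt, ch, vs, br, dv, k2, aux_t)
        for i in range(NSTATE):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(ct + 0.5 * dt, period, yt, ch, vs, br, dv, k3, aux_t)
        for i in range(NSTATE):
            yt[i] = y[i] + dt * k3[i]
        _rhs(ct + dt, period, yt, ch, vs, br, dv, k4, aux_t)
        for i in range(NSTATE):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # diode clamp: closed valves carry no reverse flow
        for i in range(IQ_AV, IQ_TV + 1):
            if y[i] < 0.0:
                y[i] = 0.0

        t += dt
        ct += dt
        step_in_beat += 1

        if ct >= period:
            # finalize beat metrics
            beatm[beat, BM_PERIOD] = period
            beatm[beat, BM_MAP] = acc_map / acc_time
            beatm[beat, BM_PAP] = acc_pap / acc_time
            beatm[beat, BM_LAP] = acc_lap / acc_time
            beatm[beat, BM_RAP] = acc_rap / acc_time
            beatm[beat, BM_EDV] = vmax
            beatm[beat, BM_ESV] = vmin
            beatm[beat, BM_CO] = acc_qsys / acc_time
            beatm[beat, BM_QPUMP] = acc_qpump / acc_time
            beatm[beat, BM_QPUMP_MIN] = qpump_min
            beatm[beat, BM_QIASD] = acc_qiasd / acc_time
            beatm[beat, BM_VSHIFT] = y[IB_VOL]
            sv_hist[beat] = vmax - vmin
            map_hist[beat] = acc_map / acc_time
            lap_hist[beat] = acc_lap / acc_time

            acc_time = 0.0
            acc_map = 0.0
            acc_pap = 0.0
            acc_lap = 0.0
            acc_rap = 0.0
            acc_qsys = 0.0
            acc_qpump = 0.0
            acc_qiasd = 0.0
            vmax = -1.0e30
            vmin = 1.0e30
            qpump_min = 1.0e30

            ct -= period
            # afferent pressure signal: beat-mean MAP smoothed across
            # beats (unbiased fixed point, first-order damping)
            k = 1.0 - np.exp(-period / br[BR_TAU_MAP])
            y[IB_MAPF] += k * (beatm[beat, BM_MAP] - y[IB_MAPF])
            if baro_on:
                period = _period_from_map(y[IB_MAPF], br)
            beat += 1
            step_in_beat = 0

            if recording:
                rec_beats_left -= 1
                if rec_beats_left <= 0:
                    break
            elif beat >= min_beats and beat >= conv_window + 1:
                stable = True
                for b in range(beat - conv_window, beat):
                    ds = abs(sv_hist[b] - sv_hist[b - 1]) / max(abs(sv_hist[b - 1]), 1.0)
                    dm = abs(map_hist[b] - map_hist[b - 1]) / max(abs(map_hist[b - 1]), 1.0)
                    dl = abs(lap_hist[b] - lap_hist[b - 1]) / max(abs(lap_hist[b - 1]), 1.0)
                    if ds > conv_tol or dm > conv_tol or dl > conv_tol:
                        stable = False
                        break
                if stable:
                    converged = True
                    recording = True
                    rec_beats_left = n_rec_beats
            if (not recording) and beat >= max_beats - n_rec_beats:
                # out of budget: record the final beats anyway, flagged
                recording = True
                rec_beats_left = n_rec_beats

    return rec[:n_rec], n_rec, beatm[:beat], beat, converged
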