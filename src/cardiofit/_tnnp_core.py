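"""Numerical core of the ten Tusscher-Noble-Noble-Panfilov (2004) epicardial model.

All kernels are numba-jitted scalar loops operating on raw float64 arrays:
``y`` is the 17-component state vector and ``p`` the 16-component vector of
scalable parameters (see :data:`PARAM_NAMES`).  Voltages are mV, time is ms,
currents are pA/pF, concentrations are mM.

Gating variables are advanced with the Rush-Larsen exponential scheme and
voltage/concentrations with forward Euler, the integration method published
with the model itself; the default step is 20 us.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# --- scalable parameters, in the order used throughout the package ---
PARAM_NAMES = (
    "g_Na", "g_bNa", "g_CaL", "g_bCa", "g_to", "g_Kr", "g_Ks", "g_K1",
    "g_pK", "k_NaK", "k_NaCa", "a_rel", "c_rel", "V_leak", "V_max_up",
    "k_pCa",
)

#: published (control) values of the scalable parameters, epicardial variant
CONTROL_VALUES = (
    14.838,     # g_Na      nS/pF
    0.00029,    # g_bNa     nS/pF
    0.000175,   # g_CaL     cm^3/(uF s)
    0.000592,   # g_bCa     nS/pF
    0.294,      # g_to      nS/pF
    0.096,      # g_Kr      nS/pF
    0.245,      # g_Ks      nS/pF
    5.405,      # g_K1      nS/pF
    0.0146,     # g_pK      nS/pF
    1.362,      # k_NaK     pA/pF
    1000.0,     # k_NaCa    pA/pF
    0.016464,   # a_rel     mM/ms
    0.008232,   # c_rel     mM/ms
    0.00008,    # V_leak    1/ms
    0.000425,   # V_max_up  mM/ms
    0.825,      # k_pCa     pA/pF
)

STATE_NAMES = (
    "V_m", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "fCa",
    "g", "Ca_i", "Ca_SR", "Na_i", "K_i",
)

#: published resting state (epicardial)
INITIAL_STATE = (
    -86.2,   # V_m
    0.0,     # m
    0.75,    # h
    0.75,    # j
    0.0,     # xr1
    1.0,     # xr2
    0.0,     # xs
    0.0,     # r
    1.0,     # s
    0.0,     # d
    1.0,     # f
    1.0,     # fCa
    1.0,     # g
    0.0002,  # Ca_i
    0.2,     # Ca_SR
    11.6,    # Na_i
    138.3,   # K_i
)

GATE_INDICES = tuple(range(1, 13))
N_STATE = 17
N_PARAM = 16

CURRENT_NAMES = (
    "I_Na", "I_bNa", "I_CaL", "I_bCa", "I_to", "I_Kr", "I_Ks", "I_K1",
    "I_pK", "I_NaK", "I_NaCa", "I_pCa",
)

# fixed model constants
_R = 8314.472
_T = 310.0
_F = 96485.3415
_RTONF = _R * _T / _F          # ~26.7137 mV
_KO = 5.4
_CAO = 2.0
_NAO = 140.0
_VC = 0.016404
_VSR = 0.001094
_BUFC = 0.15
_KBUFC = 0.001
_BUFSR = 10.0
_KBUFSR = 0.3
_KUP = 0.00025
_CAPACITANCE = 0.185
_PKNA = 0.03
_KMK = 1.0
_KMNA = 40.0
_KMNAI = 87.5
_KMCA = 1.38
_KSAT = 0.1
_GAMMA = 0.35
_KPCA = 0.0005
_B_REL = 0.25
_TAU_FCA = 2.0
_TAU_G = 2.0


@njit(cache=True)
def currents(y, p):
    """All twelve membrane currents (pA/pF) at state ``y``, parameters ``p``."""
    v = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    xr1 = y[4]
    xr2 = y[5]
    xs = y[6]
    r = y[7]
    s = y[8]
    d = y[9]
    f = y[10]
    fca = y[11]
    cai = y[13]
    nai = y[15]
    ki = y[16]

    ek = _RTONF * math.log(_KO / ki)
    ena = _RTONF * math.log(_NAO / nai)
    eks = _RTONF * math.log((_KO + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * math.log(_CAO / cai)

    out = np.empty(12)
    # fast sodium
    out[0] = p[0] * m * m * m * h * j * (v - ena)
    # background sodium
    out[1] = p[1] * (v - ena)
    # L-type calcium (GHK-like driving term); limit at v -> 0
    e2v = 2.0 * v / _RTONF
    if abs(e2v) < 1e-7:
        ghk = 2.0 * _F * (cai - 0.341 * _CAO) * (1.0 + 0.5 * e2v)
    else:
        ghk = 4.0 * v * (_F / _RTONF) * (cai * math.exp(e2v) - 0.341 * _CAO) / (
            math.exp(e2v) - 1.0
        )
    out[2] = p[2] * d * f * fca * ghk
    # background calcium
    out[3] = p[3] * (v - eca)
    # transient outward
    out[4] = p[4] * r * s * (v - ek)
    # rapid delayed rectifier
    out[5] = p[5] * math.sqrt(_KO / 5.4) * xr1 * xr2 * (v - ek)
    # slow delayed rectifier
    out[6] = p[6] * xs * xs * (v - eks)
    # inward rectifier
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (
        3.0 * math.exp(0.0002 * (v - ek + 100.0)) + math.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - ek)))
    out[7] = p[7] * ak1 / (ak1 + bk1) * (v - ek)
    # plateau potassium
    out[8] = p[8] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    # Na/K pump
    out[9] = (
        p[9]
        * (_KO / (_KO + _KMK))
        * (nai / (nai + _KMNA))
        / (1.0 + 0.1245 * math.exp(-0.1 * v / _RTONF) + 0.0353 * math.exp(-v / _RTONF))
    )
    # Na/Ca exchanger
    out[10] = (
        p[10]
        * (
            math.exp(_GAMMA * v / _RTONF) * nai * nai * nai * _CAO
            - math.exp((_GAMMA - 1.0) * v / _RTONF) * _NAO * _NAO * _NAO * cai * 2.5
        )
        / (
            (_KMNAI * _KMNAI * _KMNAI + _NAO * _NAO * _NAO)
            * (_KMCA + _CAO)
            * (1.0 + _KSAT * math.exp((_GAMMA - 1.0) * v / _RTONF))
        )
    )
    # sarcolemmal Ca pump
    out[11] = p[15] * cai / (_KPCA + cai)
    return out


@njit(cache=True)
def total_current(y, p):
    """Total ionic current I_m (pA/pF)."""
    c = currents(y, p)
    tot = 0.0
    for k in range(12):
        tot += c[k]
    return tot


@njit(cache=True)
def _gate_targets(v, cai):
    """Steady states and time constants of the twelve gates at voltage ``v``."""
    inf = np.empty(12)
    tau = np.empty(12)

    # m
    inf[0] = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((v - 50.0) / 200.0)
    )
    tau[0] = am * bm

    # h
    inf[1] = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    tau[1] = 1.0 / (ah + bh)

    # j
    inf[2] = inf[1]
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # xr1
    inf[3] = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tau[3] = axr1 * bxr1

    # xr2
    inf[4] = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau[4] = axr2 * bxr2

    # xs
    inf[5] = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau[5] = axs * bxs

    # r
    inf[6] = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau[6] = 9.5 * math.exp(-(v + 40.0) * (v + 40.0) / 1800.0) + 0.8

    # s (epicardial)
    inf[7] = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    tau[7] = (
        85.0 * math.exp(-(v + 45.0) * (v + 45.0) / 320.0)
        + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0))
        + 3.0
    )

    # d
    inf[8] = 1.0 / (1.0 + math.exp((-5.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    cd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau[8] = ad * bd + cd

    # f
    inf[9] = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau[9] = (
        1125.0 * math.exp(-(v + 27.0) * (v + 27.0) / 240.0)
        + 80.0
        + 165.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    )

    # fCa (calcium dependent)
    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    cfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    inf[10] = (afca + bfca + cfca + 0.23) / 1.46
    tau[10] = _TAU_FCA

    # g (calcium release gate)
    if cai < 0.00035:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    tau[11] = _TAU_G

    return inf, tau


@njit(cache=True)
def rhs(t, y, p, i_stim):
    """Time derivative of the full state; dV/dt = -(I_ion + I_stim)."""
    v = y[0]
    cai = y[13]
    casr = y[14]
    d = y[9]
    g = y[12]

    cur = currents(y, p)
    iion = 0.0
    for k in range(12):
        iion += cur[k]

    dy = np.empty(N_STATE)
    dy[0] = -(iion + i_stim)

    inf, tau = _gate_targets(v, cai)
    for k in range(12):
        dy[1 + k] = (inf[k] - y[1 + k]) / tau[k]
    # fCa and g only relax when not frozen (freeze during depolarized upstates)
    if inf[10] > y[11] and v > -60.0:
        dy[11] = 0.0
    if inf[11] > y[12] and v > -60.0:
        dy[12] = 0.0

    # calcium subsystem
    irel = (p[11] * casr * casr / (_B_REL * _B_REL + casr * casr) + p[12]) * d * g
    ileak = p[13] * (casr - cai)
    iup = p[14] / (1.0 + (_KUP * _KUP) / (cai * cai))
    ca_in = -(cur[2] + cur[3] + cur[11] - 2.0 * cur[10]) / (
        2.0 * _VC * _F
    ) * _CAPACITANCE
    phi_c = 1.0 / (1.0 + _BUFC * _KBUFC / ((cai + _KBUFC) * (cai + _KBUFC)))
    dy[13] = phi_c * (ca_in + ileak - iup + irel)
    phi_sr = 1.0 / (1.0 + _BUFSR * _KBUFSR / ((casr + _KBUFSR) * (casr + _KBUFSR)))
    dy[14] = phi_sr * (_VC / _VSR) * (iup - irel - ileak)

    # sodium and potassium bookkeeping
    dy[15] = -(cur[0] + cur[1] + 3.0 * cur[9] + 3.0 * cur[10]) / (
        _VC * _F
    ) * _CAPACITANCE
    dy[16] = -(
        i_stim + cur[7] + cur[4] + cur[5] + cur[6] - 2.0 * cur[9] + cur[8]
    ) / (_VC * _F) * _CAPACITANCE
    return dy


@njit(cache=True)
def step(y, p, dt, i_stim, clamped):
    """Advance ``y`` in place by ``dt``: Rush-Larsen gates, Euler otherwise.

    When ``clamped`` is true V_m is held fixed (no capacitive current) while
    every other state variable keeps evolving.
    """
    v = y[0]
    cai = y[13]
    casr = y[14]
    d_gate = y[9]
    g_gate = y[12]

    cur = currents(y, p)
    iion = 0.0
    for k in range(12):
        iion += cur[k]

    inf, tau = _gate_targets(v, cai)
    for k in range(12):
        new = inf[k] + (y[1 + k] - inf[k]) * math.exp(-dt / tau[k])
        if k == 10 and inf[10] > y[11] and v > -60.0:
            new = y[11]
        if k == 11 and inf[11] > y[12] and v > -60.0:
            new = y[12]
        y[1 + k] = new

    irel = (p[11] * casr * casr / (_B_REL * _B_REL + casr * casr) + p[12]) * d_gate * g_gate
    ileak = p[13] * (casr - cai)
    iup = p[14] / (1.0 + (_KUP * _KUP) / (cai * cai))
    ca_in = -(cur[2] + cur[3] + cur[11] - 2.0 * cur[10]) / (
        2.0 * _VC * _F
    ) * _CAPACITANCE
    phi_c = 1.0 / (1.0 + _BUFC * _KBUFC / ((cai + _KBUFC) * (cai + _KBUFC)))
    y[13] = cai + dt * phi_c * (ca_in + ileak - iup + irel)
    phi_sr = 1.0 / (1.0 + _BUFSR * _KBUFSR / ((casr + _KBUFSR) * (casr + _KBUFSR)))
    y[14] = casr + dt * phi_sr * (_VC / _VSR) * (iup - irel - ileak)

    y[15] = y[15] - dt * (
        cur[0] + cur[1] + 3.0 * cur[9] + 3.0 * cur[10]
    ) / (_VC * _F) * _CAPACITANCE
    y[16] = y[16] - dt * (
        i_stim + cur[7] + cur[4] + cur[5] + cur[6] - 2.0 * cur[9] + cur[8]
    ) / (_VC * _F) * _CAPACITANCE

    if not clamped:
        y[0] = v - dt * (iion + i_stim)
    return iion


@njit(cache=True)
def integrate(y, p, t0, t1, dt, stim_times, stim_amp, stim_dur):
    """Advance ``y`` in place from ``t0`` to ``t1`` under periodic stimuli."""
    n = int(round((t1 - t0) / dt))
    for i in range(n):
        t = t0 + i * dt
        i_stim = 0.0
        for k in range(stim_times.shape[0]):
            if stim_times[k] <= t < stim_times[k] + stim_dur:
                i_stim = stim_amp
                break
        step(y, p, dt, i_stim, False)


@njit(cache=True)
def record(y, p, t0, t1, dt, stim_times, stim_amp, stim_dur, sample_every,
           out_states):
    """Like :func:`integrate` but snapshots the state every ``sample_every`` steps.

    ``out_states`` must have shape ``(n_steps // sample_every + 1, 17)``.
    The first row is the state at ``t0``.
    """
    n = int(round((t1 - t0) / dt))
    row = 0
    for i in range(n + 1):
        if i % sample_every == 0:
            for k in range(N_STATE):
                out_states[row, k] = y[k]
            row += 1
        if i == n:
            break
        t = t0 + i * dt
        i_stim = 0.0
        for k in range(stim_times.shape[0]):
            if stim_times[k] <= t < stim_times[k] + stim_dur:
                i_stim = stim_amp
                break
        step(y, p, dt, i_stim, False)


@njit(cache=True)
def clamp(y, p, duration, dt, v_clamp, sample_every, out_i):
    """Hold V_m at ``v_clamp`` for ``duration`` ms, recording I_m.

    ``out_i[r]`` is the total ionic current at time ``r * sample_every * dt``
    after clamp onset (so ``out_i[0]`` is the instantaneous post-step current).
    """
    y[0] = v_clamp
    n = int(round(duration / dt))
    row = 0
    for i in range(n + 1):
        if i % sample_every == 0:
            out_i[row] = total_current(y, p)
            row += 1
        if i == n:
            break
        step(y, p, dt, 0.0, True)
        y[0] = v_clamp


@njit(cache=True)
def cable(states, p, t0, t1, dt, lam, stim_start, stim_dur, stim_amp,
          stim_lo, stim_hi, sample_every, out_v, act_time, act_thresh):
    """Monodomain 1D cable with no-flux ends, operator splitting.

    states : (n_nodes, 17) array updated in place.
    lam : D * dt / dx^2 (dimensionless explicit-diffusion number).
    stim_lo:stim_hi : node slice receiving transmembrane stimulus.
    out_v : (n_samples, n_nodes) voltage record, row 0 at t0.
    act_time : per-node first upward crossing of ``act_thresh`` (ms), -1 if none.
    """
    n_nodes = states.shape[0]
    n = int(round((t1 - t0) / dt))
    vold = np.empty(n_nodes)
    row = 0
    for i in range(n + 1):
        if i % sample_every == 0 and row < out_v.shape[0]:
            for m in range(n_nodes):
                out_v[row, m] = states[m, 0]
            row += 1
        if i == n:
            break
        t = t0 + i * dt
        # diffusion on V; zero-flux faces (conservative finite-volume form)
        for m in range(n_nodes):
            vold[m] = states[m, 0]
        for m in range(n_nodes):
            vl = vold[m - 1] if m > 0 else vold[0]
            vr = vold[m + 1] if m < n_nodes - 1 else vold[n_nodes - 1]
            states[m, 0] = vold[m] + lam * (vl - 2.0 * vold[m] + vr)
        # ionic step per node
        for m in range(n_nodes):
            i_stim = 0.0
            if stim_lo <= m < stim_hi and stim_start <= t < stim_start + stim_dur:
                i_stim = stim_amp
            prev_v = states[m, 0]
            step(states[m], p, dt, i_stim, False)
            if act_time[m] < 0.0 and prev_v < act_thresh <= states[m, 0]:
                act_time[m] = t + dt
        # instability guard
        for m in range(n_nodes):
            if abs(states[m, 0]) > 200.0:
                return -1
    return 0
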