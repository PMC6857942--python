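"""Compiled kernel for the ten Tusscher–Noble–Noble–Panfilov (2004) epicardial model.

The model is a 17-state ODE system describing a human left-ventricular
epicardial myocyte: membrane voltage, 12 Hodgkin–Huxley-type gates, and the
intracellular Ca2+, SR Ca2+, Na+ and K+ concentrations.  All equation
constants are the published nominal values; tunable maximal conductances and
rates enter through a premultiplied parameter vector so that scale factors
can be applied without touching the equations.

Integration uses the fixed-step operator-split scheme standard for this
model: Rush–Larsen exponential updates for the gates and forward Euler for
voltage and concentrations.  Everything here is numba-compiled; the public
API lives in :mod:`cardiofit.models` and :mod:`cardiofit.pacing`.

Units: mV, ms, pA/pF, mM (the model's native convention).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- indices into the premultiplied parameter vector -------------------------
# The first 16 slots are the tunable maximal conductances/rates (already
# multiplied by their scale factors); slot 16 is extracellular [K+] in mM.
P_GNA, P_GCAL, P_GBNA, P_GBCA, P_GKR, P_GTO, P_GK1, P_GKS, P_GPK, P_PNAK, \
    P_KNACA, P_GPCA, P_VMAXUP, P_CREL, P_AREL, P_VLEAK, P_KO = range(17)

#: nominal epicardial values, same order as the P_* indices (excluding [K+]o)
NOMINAL = np.array([
    14.838,     # G_Na      nS/pF
    0.000175,   # G_CaL     cm^3 uF^-1 ms^-1
    0.00029,    # G_bNa     nS/pF
    0.000592,   # G_bCa     nS/pF
    0.096,      # G_Kr      nS/pF
    0.294,      # G_to      nS/pF (epicardial)
    5.405,      # G_K1      nS/pF
    0.245,      # G_Ks      nS/pF (epicardial)
    0.0146,     # G_pK      nS/pF
    1.362,      # P_NaK     pA/pF
    1000.0,     # k_NaCa    pA/pF
    0.825,      # G_pCa     pA/pF
    0.000425,   # V_maxup   mM/ms
    0.008232,   # c_rel     mM/ms
    0.016464,   # a_rel     mM/ms
    8e-5,       # V_leak    ms^-1
])

KO_NOMINAL = 5.4  # mM

# state layout: V, m, h, j, d, f, fCa, r, s, xr1, xr2, xs, g, Cai, CaSR, Nai, Ki
N_STATE = 17
V_INDEX = 0
STATE_NAMES = ("vm_mV", "m", "h", "j", "d", "f", "fca", "r", "s", "xr1",
               "xr2", "xs", "g", "cai_mM", "casr_mM", "nai_mM", "ki_mM")

#: published resting initial conditions (epicardial variant)
INITIAL_STATE = np.array([
    -86.2,    # V (mV)
    0.0,      # m
    0.75,     # h
    0.75,     # j
    0.0,      # d
    1.0,      # f
    1.0,      # fCa
    0.0,      # r
    1.0,      # s
    0.0,      # xr1
    1.0,      # xr2
    0.0,      # xs
    1.0,      # g
    0.0002,   # Cai (mM)
    0.2,      # CaSR (mM)
    11.6,     # Nai (mM)
    138.3,    # Ki (mM)
])

CAPACITANCE_PF = 185.0  # whole-cell capacitance implied by Cm = 0.185 nF

# fixed physical / geometric constants
_R = 8314.472       # mJ mol^-1 K^-1
_T = 310.0          # K
_F = 96485.3415     # C mol^-1
_RTONF = _R * _T / _F
_CM = 0.185         # uF (membrane capacitance used in flux bookkeeping)
_VC = 0.016404      # um^3 (scaled cytoplasmic volume)
_VSR = 0.001094     # um^3 (scaled SR volume)
_NAO = 140.0        # mM
_CAO = 2.0          # mM
_PKNA = 0.03
_KM_K = 1.0
_KM_NA = 40.0
_KM_NAI = 87.5
_KM_CA = 1.38
_KSAT = 0.1
_GAMMA = 0.35
_ALPHA_NACA = 2.5
_KPCA = 0.0005
_KUP = 0.00025
_BREL = 0.25
_BUFC = 0.15
_KBUFC = 0.001
_BUFSR = 10.0
_KBUFSR = 0.3
_TAU_G = 2.0
_TAU_FCA = 2.0


def make_param_vector(scales: np.ndarray, ko_mM: float = KO_NOMINAL) -> np.ndarray:
    """Premultiply nominal conductances/rates by 16 scale factors."""
    p = np.empty(17)
    p[:16] = NOMINAL * np.asarray(scales, dtype=np.float64)
    p[16] = ko_mM
    return p


@njit(cache=True)
def total_ionic_current(y, p):
    """Total membrane current I_m (pA/pF) at a given state."""
    V = y[0]
    m = y[1]; h = y[2]; j = y[3]; d = y[4]; f = y[5]; fca = y[6]
    r = y[7]; s = y[8]; xr1 = y[9]; xr2 = y[10]; xs = y[11]
    cai = y[13]; nai = y[15]; ki = y[16]
    ko = p[16]

    ek = _RTONF * np.log(ko / ki)
    ena = _RTONF * np.log(_NAO / nai)
    eks = _RTONF * np.log((ko + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * np.log(_CAO / cai)

    ina = p[0] * m * m * m * h * j * (V - ena)

    vfrt = V * _F / (_R * _T)
    if abs(V) > 1e-6:
        e2 = np.exp(2.0 * vfrt)
        ical = p[1] * d * f * fca * 4.0 * V * (_F * _F / (_R * _T)) * \
            (cai * e2 - 0.341 * _CAO) / (e2 - 1.0)
    else:  # removable singularity at V = 0
        ical = p[1] * d * f * fca * 2.0 * _F * (cai - 0.341 * _CAO)

    ito = p[5] * r * s * (V - ek)
    ikr = p[4] * np.sqrt(ko / 5.4) * xr1 * xr2 * (V - ek)
    iks = p[7] * xs * xs * (V - eks)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0)) +
           np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = p[6] * np.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (V - ek)

    en = np.exp(_GAMMA * vfrt)
    em = np.exp((_GAMMA - 1.0) * vfrt)
    inaca = p[10] * (en * nai ** 3 * _CAO - em * _NAO ** 3 * cai * _ALPHA_NACA) / \
        ((_KM_NAI ** 3 + _NAO ** 3) * (_KM_CA + _CAO) * (1.0 + _KSAT * em))

    inak = p[9] * (ko / (ko + _KM_K)) * (nai / (nai + _KM_NA)) / \
        (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))

    ipca = p[11] * cai / (_KPCA + cai)
    ipk = p[8] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = p[2] * (V - ena)
    ibca = p[3] * (V - eca)

    return (ina + ical + ito + ikr + iks + ik1 + inaca + inak +
            ipca + ipk + ibna + ibca)


@njit(cache=True)
def _step(y, p, dt, istim, clamped):
    """Advance the state in place by one Rush–Larsen / Euler step.

    ``istim`` follows the model's sign convention (depolarizing stimulus is
    negative).  With ``clamped`` set, V is held fixed and only gates and
    concentrations evolve.
    """
    V = y[0]
    cai = y[13]; casr = y[14]

    # --- gate rates --------------------------------------------------------
    minf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + \
        0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    taum = am * bm

    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    tauh = 1.0 / (ah + bh)

    jinf = hinf
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) * \
            (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / \
            (1.0 + np.exp(-0.1378 * (V + 40.14)))
    tauj = 1.0 / (aj + bj)

    dinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    taud = ad * bd + cd

    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tauf = 1125.0 * np.exp(-(V + 27.0) ** 2 / 240.0) + 80.0 + \
        165.0 / (1.0 + np.exp((25.0 - V) / 10.0))

    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    taur = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8

    sinf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))  # epicardial
    taus = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) + \
        5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0

    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1

    xr2inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2

    xsinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    tauxs = axs * bxs

    afc = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfc = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    cfc = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fcainf = (afc + bfc + cfc + 0.23) / 1.46

    if cai < 0.00035:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)

    # --- Ca2+ fluxes -------------------------------------------------------
    irel = (p[14] * casr * casr / (_BREL * _BREL + casr * casr) + p[13]) * \
        y[4] * y[12]
    ileak = p[15] * (casr - cai)
    iup = p[12] / (1.0 + (_KUP / cai) ** 2)

    bufc_fac = 1.0 / (1.0 + _BUFC * _KBUFC / (cai + _KBUFC) ** 2)
    bufsr_fac = 1.0 / (1.0 + _BUFSR * _KBUFSR / (casr + _KBUFSR) ** 2)

    # --- membrane currents -------------------------------------------------
    ki = y[16]; nai = y[15]
    ko = p[16]
    ek = _RTONF * np.log(ko / ki)
    ena = _RTONF * np.log(_NAO / nai)
    eks = _RTONF * np.log((ko + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * np.log(_CAO / cai)
    vfrt = V * _F / (_R * _T)

    ina = p[0] * y[1] ** 3 * y[2] * y[3] * (V - ena)
    if abs(V) > 1e-6:
        e2 = np.exp(2.0 * vfrt)
        ical = p[1] * y[4] * y[5] * y[6] * 4.0 * V * (_F * _F / (_R * _T)) * \
            (cai * e2 - 0.341 * _CAO) / (e2 - 1.0)
    else:
        ical = p[1] * y[4] * y[5] * y[6] * 2.0 * _F * (cai - 0.341 * _CAO)
    ito = p[5] * y[7] * y[8] * (V - ek)
    ikr = p[4] * np.sqrt(ko / 5.4) * y[9] * y[10] * (V - ek)
    iks = p[7] * y[11] * y[11] * (V - eks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0)) +
           np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = p[6] * np.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (V - ek)
    en = np.exp(_GAMMA * vfrt)
    em = np.exp((_GAMMA - 1.0) * vfrt)
    inaca = p[10] * (en * nai ** 3 * _CAO - em * _NAO ** 3 * cai * _ALPHA_NACA) / \
        ((_KM_NAI ** 3 + _NAO ** 3) * (_KM_CA + _CAO) * (1.0 + _KSAT * em))
    inak = p[9] * (ko / (ko + _KM_K)) * (nai / (nai + _KM_NA)) / \
        (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))
    ipca = p[11] * cai / (_KPCA + cai)
    ipk = p[8] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = p[2] * (V - ena)
    ibca = p[3] * (V - eca)

    iion = (ina + ical + ito + ikr + iks + ik1 + inaca + inak +
            ipca + ipk + ibna + ibca)

    dcai = bufc_fac * ((ileak - iup + irel) -
                       (ical + ibca + ipca - 2.0 * inaca) *
                       _CM / (2.0 * _VC * _F))
    dcasr = bufsr_fac * (_VC / _VSR) * (iup - irel - ileak)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * _CM / (_VC * _F)
    dki = -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * _CM / (_VC * _F)

    # --- apply updates -----------------------------------------------------
    if not clamped:
        y[0] = V - dt * (iion + istim)

    y[1] = minf + (y[1] - minf) * np.exp(-dt / taum)
    y[2] = hinf + (y[2] - hinf) * np.exp(-dt / tauh)
    y[3] = jinf + (y[3] - jinf) * np.exp(-dt / tauj)
    y[4] = dinf + (y[4] - dinf) * np.exp(-dt / taud)
    y[5] = finf + (y[5] - finf) * np.exp(-dt / tauf)
    # fCa and g carry the model's voltage-dependent lock: the gate may not
    # recover (increase) while the membrane is depolarized
    fca_new = fcainf + (y[6] - fcainf) * np.exp(-dt / _TAU_FCA)
    if not (fcainf > y[6] and V > -60.0):
        y[6] = fca_new
    y[7] = rinf + (y[7] - rinf) * np.exp(-dt / taur)
    y[8] = sinf + (y[8] - sinf) * np.exp(-dt / taus)
    y[9] = xr1inf + (y[9] - xr1inf) * np.exp(-dt / tauxr1)
    y[10] = xr2inf + (y[10] - xr2inf) * np.exp(-dt / tauxr2)
    y[11] = xsinf + (y[11] - xsinf) * np.exp(-dt / tauxs)
    g_new = ginf + (y[12] - ginf) * np.exp(-dt / _TAU_G)
    if not (ginf > y[12] and V > -60.0):
        y[12] = g_new

    y[13] = cai + dt * dcai
    y[14] = casr + dt * dcasr
    y[15] = nai + dt * dnai
    y[16] = ki + dt * dki
    return iion


@njit(cache=True)
def integrate(y0, p, dt, n_steps, stim_amp, stim_steps, clamp_v, clamped, stride):
    """Integrate ``n_steps`` steps, recording every ``stride``-th state.

    Returns ``(record, status, fail_step)`` where record[k] is the state
    after ``k * stride`` steps (record[0] is the initial state), status is 0
    on success and 1 if the state went non-finite at step ``fail_step``.
    """
    y = y0.copy()
    if clamped:
        y[0] = clamp_v
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, N_STATE))
    out[0] = y
    k = 1
    for i in range(n_steps):
        istim = -stim_amp if i < stim_steps else 0.0
        _step(y, p, dt, istim, clamped)
        if (i + 1) % stride == 0:
            if not np.isfinite(y[0]):
                return out[:k], 1, i + 1
            out[k] = y
            k += 1
    if not (np.isfinite(y[0]) and np.isfinite(y[13]) and np.isfinite(y[16])):
        return out[:k], 1, n_steps
    return out[:k], 0, n_steps


@njit(cache=True)
def rhs(t, y, p, istim):
    """Free-running right-hand side (dy/dt) for cross-checks with generic
    ODE solvers.  Gate derivatives use the same rates as :func:`_step`."""
    dy = np.empty(N_STATE)
    iion = total_ionic_current(y, p)
    V = y[0]
    cai = y[13]

    dy[0] = -(iion + istim)

    minf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + \
        0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    dy[1] = (minf - y[1]) / (am * bm)

    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    dy[2] = (hinf - y[2]) * (ah + bh)

    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        aj = (-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V)) * \
            (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / \
            (1.0 + np.exp(-0.1378 * (V + 40.14)))
    dy[3] = (hinf - y[3]) * (aj + bj)

    dinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    cd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    dy[4] = (dinf - y[4]) / (ad * bd + cd)

    finf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tauf = 1125.0 * np.exp(-(V + 27.0) ** 2 / 240.0) + 80.0 + \
        165.0 / (1.0 + np.exp((25.0 - V) / 10.0))
    dy[5] = (finf - y[5]) / tauf

    afc = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfc = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    cfc = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    fcainf = (afc + bfc + cfc + 0.23) / 1.46
    if fcainf > y[6] and V > -60.0:
        dy[6] = 0.0
    else:
        dy[6] = (fcainf - y[6]) / _TAU_FCA

    rinf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    taur = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    dy[7] = (rinf - y[7]) / taur

    sinf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    taus = 85.0 * np.exp(-(V + 45.0) ** 2 / 320.0) + \
        5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0
    dy[8] = (sinf - y[8]) / taus

    xr1inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    dy[9] = (xr1inf - y[9]) / (axr1 * bxr1)

    xr2inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    dy[10] = (xr2inf - y[10]) / (axr2 * bxr2)

    xsinf = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 60.0) / 20.0))
    dy[11] = (xsinf - y[11]) / (axs * bxs)

    if cai < 0.00035:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    if ginf > y[12] and V > -60.0:
        dy[12] = 0.0
    else:
        dy[12] = (ginf - y[12]) / _TAU_G

    casr = y[14]
    irel = (p[14] * casr * casr / (_BREL * _BREL + casr * casr) + p[13]) * \
        y[4] * y[12]
    ileak = p[15] * (casr - cai)
    iup = p[12] / (1.0 + (_KUP / cai) ** 2)
    bufc_fac = 1.0 / (1.0 + _BUFC * _KBUFC / (cai + _KBUFC) ** 2)
    bufsr_fac = 1.0 / (1.0 + _BUFSR * _KBUFSR / (casr + _KBUFSR) ** 2)

    ki = y[16]; nai = y[15]
    ko = p[16]
    ek = _RTONF * np.log(ko / ki)
    ena = _RTONF * np.log(_NAO / nai)
    eks = _RTONF * np.log((ko + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * np.log(_CAO / cai)
    vfrt = V * _F / (_R * _T)
    ina = p[0] * y[1] ** 3 * y[2] * y[3] * (V - ena)
    if abs(V) > 1e-6:
        e2 = np.exp(2.0 * vfrt)
        ical = p[1] * y[4] * y[5] * y[6] * 4.0 * V * (_F * _F / (_R * _T)) * \
            (cai * e2 - 0.341 * _CAO) / (e2 - 1.0)
    else:
        ical = p[1] * y[4] * y[5] * y[6] * 2.0 * _F * (cai - 0.341 * _CAO)
    ito = p[5] * y[7] * y[8] * (V - ek)
    ikr = p[4] * np.sqrt(ko / 5.4) * y[9] * y[10] * (V - ek)
    iks = p[7] * y[11] * y[11] * (V - eks)
    ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    bk1 = (3.0 * np.exp(0.0002 * (V - ek + 100.0)) +
           np.exp(0.1 * (V - ek - 10.0))) / (1.0 + np.exp(-0.5 * (V - ek)))
    ik1 = p[6] * np.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (V - ek)
    en = np.exp(_GAMMA * vfrt)
    em = np.exp((_GAMMA - 1.0) * vfrt)
    inaca = p[10] * (en * nai ** 3 * _CAO - em * _NAO ** 3 * cai * _ALPHA_NACA) / \
        ((_KM_NAI ** 3 + _NAO ** 3) * (_KM_CA + _CAO) * (1.0 + _KSAT * em))
    inak = p[9] * (ko / (ko + _KM_K)) * (nai / (nai + _KM_NA)) / \
        (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))
    ipca = p[11] * cai / (_KPCA + cai)
    ipk = p[8] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    ibna = p[2] * (V - ena)
    ibca = p[3] * (V - eca)

    dy[13] = bufc_fac * ((ileak - iup + irel) -
                         (ical + ibca + ipca - 2.0 * inaca) *
                         _CM / (2.0 * _VC * _F))
    dy[14] = bufsr_fac * (_VC / _VSR) * (iup - irel - ileak)
    dy[15] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * _CM / (_VC * _F)
    dy[16] = -(istim + ik1 + ito + ikr + iks - 2.0 * inak + ipk) * _CM / (_VC * _F)
    return dy
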