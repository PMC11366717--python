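"""ten Tusscher--Panfilov (2006) human ventricular membrane kinetics.

State layout (per cell, ``NSTATE`` floats besides Vm):

====  ==========  =========================================================
idx   name        meaning
====  ==========  =========================================================
0-10  gates       m, h, j, d, f, f2, r, s, xr1, xr2, xs (voltage gates)
11    fcass       Ca-subspace dependent ICaL gate
12    rbar        ryanodine-receptor adaptation variable
13    cai         cytosolic Ca2+ (mM)
14    cass        dyadic-subspace Ca2+ (mM)
15    casr        sarcoplasmic-reticulum Ca2+ (mM)
16    nai         intracellular Na+ (mM)
17    ki          intracellular K+ (mM)
====  ==========  =========================================================

Voltage gates are advanced with the exponential (Rush--Larsen) update,
which is exact for a gate with frozen rate coefficients over one step;
``fcass`` and ``rbar`` use the same exact exponential form with their
Ca-dependent coefficients frozen over the step; concentrations use forward
Euler.  A stretch-activated-channel current ``ISAC = gsac * (Vm - esac)``
is added to the ionic current sum.

The slow delayed rectifier conductance is ``GKS[variant] * GKS_ADJUST *
iks_scale``: ``iks_scale`` is the heterogeneity scaling factor (1 at the
basal endocardium up to 4 at the apical epicardium) and ``GKR_ADJUST`` /
``GKS_ADJUST`` are the fixed baseline calibration factors documented in
:mod:`sacsim.cell.calibration`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 18
N_VGATES = 11

VARIANT_EPI = 0
VARIANT_ENDO = 1
VARIANT_MID = 2
VARIANTS = {"epi": VARIANT_EPI, "endo": VARIANT_ENDO, "mid": VARIANT_MID}

# physical constants
R_GAS = 8314.472  # mJ/(mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY

# extracellular concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# maximal conductances (nS/pF) and permeabilities
G_NA = 14.838
G_K1 = 5.405
G_KR = 0.153
G_KS_EPI = 0.392
G_KS_ENDO = 0.392
G_KS_MID = 0.098
G_TO_EPI = 0.294
G_TO_ENDO = 0.073
G_TO_MID = 0.294
G_CAL = 3.980e-5
G_BNA = 0.00029
G_BCA = 0.000592
G_PCA = 0.1238
K_PCA = 0.0005
G_PK = 0.0146
P_KNA = 0.03

# Na/K pump and Na/Ca exchanger
P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0
K_NACA = 1000.0
K_SAT = 0.1
ALPHA_NACA = 2.5
GAMMA_NACA = 0.35
KM_NAI = 87.5
KM_CA = 1.38

# calcium handling
VMAX_UP = 0.006375
K_UP = 0.00025
V_REL = 0.102
V_XFER = 0.0038
V_LEAK = 0.00036
K1_PRIME = 0.15
K2_PRIME = 0.045
K3_REL = 0.060
K4_REL = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

# geometry of the single-cell compartments
CAPACITANCE = 0.185  # uF, as in the published formulation
V_C = 0.016404
V_SR = 0.001094
V_SS = 0.00005468

# published resting state (prepacing relaxes this onto the limit cycle)
V_REST_INIT = -85.23
STATE_INIT = np.array(
    [
        0.00172,  # m
        0.7444,  # h
        0.7045,  # j
        3.373e-5,  # d
        0.7888,  # f
        0.9755,  # f2
        2.42e-8,  # r
        0.999998,  # s
        0.00621,  # xr1
        0.4712,  # xr2
        0.0095,  # xs
        0.9953,  # fcass
        0.9073,  # rbar
        0.000126,  # cai
        0.00036,  # cass
        3.64,  # casr
        8.604,  # nai
        136.89,  # ki
    ]
)

# baseline-variant calibration (see sacsim.cell.calibration)
GKR_ADJUST_DEFAULT = 1.0
GKS_ADJUST_DEFAULT = 1.0


@njit(cache=True)
def gate_rates(v, variant, inf, tau):
    """Steady states and time constants of the 11 voltage gates at ``v``.

    Fills ``inf`` and ``tau`` (length 11 arrays) in the state ordering
    m, h, j, d, f, f2, r, s, xr1, xr2, xs.
    """
    # INa gates
    inf[0] = 1.0 / ((1.0 + np.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + np.exp((v - 50.0) / 200.0)
    )
    tau[0] = am * bm

    inf[1] = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    tau[1] = 1.0 / (ah + bh)

    inf[2] = inf[1]
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        aj = (
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + np.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # ICaL voltage gates
    inf[3] = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau[3] = ad * bd + gd

    inf[4] = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau[4] = (
        1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0))
        + 20.0
    )

    inf[5] = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau[5] = (
        562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0))
    )

    # Ito gates
    inf[6] = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau[6] = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8

    if variant == VARIANT_ENDO:
        inf[7] = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
        tau[7] = 1000.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    else:
        inf[7] = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
        tau[7] = (
            85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0))
            + 3.0
        )

    # IKr gates
    inf[8] = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau[8] = axr1 * bxr1

    inf[9] = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau[9] = axr2 * bxr2

    # IKs gate
    inf[10] = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    tau[10] = axs * bxs + 80.0


def build_gate_tables(dt, variant, v_min=-120.0, v_max=90.0, dv=0.01):
    """Tabulate gate steady states and ``exp(-dt/tau)`` on a Vm grid.

    The tables are tied to one reaction step ``dt``; the tissue kernel
    interpolates them linearly in Vm.
    """
    n = int(round((v_max - v_min) / dv)) + 1
    vs = v_min + dv * np.arange(n)
    inf_tab = np.empty((n, N_VGATES))
    exp_tab = np.empty((n, N_VGATES))
    inf = np.empty(N_VGATES)
    tau = np.empty(N_VGATES)
    for i, v in enumerate(vs):
        gate_rates(v, variant, inf, tau)
        inf_tab[i] = inf
        exp_tab[i] = np.exp(-dt / tau)
    return v_min, 1.0 / dv, inf_tab, exp_tab


@njit(cache=True, fastmath=True)
def _step_one(v, s, dt, istim, gsac, esac, gks_eff, gto, gkr, variant,
              use_table, v0, dvinv, inf_tab, exp_tab):
    """Advance one cell by one reaction step; returns the new Vm."""
    ek = RTONF * np.log(K_O / s[17])
    ena = RTONF * np.log(NA_O / s[16])
    eks = RTONF * np.log((K_O + P_KNA * NA_O) / (s[17] + P_KNA * s[16]))
    eca = 0.5 * RTONF * np.log(CA_O / s[13])

    # ----- membrane currents from the current state -----
    ina = G_NA * s[0] ** 3 * s[1] * s[2] * (v - ena)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (
        3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + np.exp(-0.5 * (v - ek)))
    ik1 = G_K1 * np.sqrt(K_O / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

    ito = gto * s[6] * s[7] * (v - ek)
    ikr = gkr * np.sqrt(K_O / 5.4) * s[8] * s[9] * (v - ek)
    iks = gks_eff * s[10] ** 2 * (v - eks)

    vf_rt = (v - 15.0) * FARADAY / (R_GAS * TEMP)
    if np.abs(vf_rt) < 1e-6:
        ecal = 0.5 * (0.25 * s[14] * (1.0 + 2.0 * vf_rt) - CA_O) * (
            2.0 + 2.0 * vf_rt
        )
    else:
        e2 = np.exp(2.0 * vf_rt)
        ecal = 4.0 * vf_rt * (0.25 * s[14] * e2 - CA_O) / (e2 - 1.0)
    ical = G_CAL * s[3] * s[4] * s[5] * s[11] * FARADAY * ecal

    vfrt = v * FARADAY / (R_GAS * TEMP)
    inaca = (
        K_NACA
        * (
            np.exp(GAMMA_NACA * vfrt) * s[16] ** 3 * CA_O
            - np.exp((GAMMA_NACA - 1.0) * vfrt) * NA_O ** 3 * s[13] * ALPHA_NACA
        )
        / (
            (KM_NAI ** 3 + NA_O ** 3)
            * (KM_CA + CA_O)
            * (1.0 + K_SAT * np.exp((GAMMA_NACA - 1.0) * vfrt))
        )
    )
    inak = (
        P_NAK
        * K_O
        * s[16]
        / (
            (K_O + K_MK)
            * (s[16] + K_MNA)
            * (1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt))
        )
    )
    ipca = G_PCA * s[13] / (s[13] + K_PCA)
    ipk = G_PK * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
    ibna = G_BNA * (v - ena)
    ibca = G_BCA * (v - eca)
    isac = gsac * (v - esac)

    iion = (
        ina + ik1 + ito + ikr + iks + ical + inaca + inak
        + ipca + ipk + ibna + ibca + isac
    )

    # ----- calcium handling fluxes -----
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / s[15]) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_rel = k1 * s[14] ** 2 * s[12] / (K3_REL + k1 * s[14] ** 2)
    irel = V_REL * o_rel * (s[15] - s[14])
    ileak = V_LEAK * (s[15] - s[13])
    iup = VMAX_UP / (1.0 + (K_UP / s[13]) ** 2)
    ixfer = V_XFER * (s[14] - s[13])

    # ----- exact exponential updates for gating variables -----
    if use_table:
        x = (v - v0) * dvinv
        i0 = int(x)
        if i0 < 0:
            i0 = 0
        nmax = inf_tab.shape[0] - 2
        if i0 > nmax:
            i0 = nmax
        w = x - i0
        for g in range(N_VGATES):
            gi = inf_tab[i0, g] * (1.0 - w) + inf_tab[i0 + 1, g] * w
            ge = exp_tab[i0, g] * (1.0 - w) + exp_tab[i0 + 1, g] * w
            s[g] = gi + (s[g] - gi) * ge
    else:
        inf = np.empty(N_VGATES)
        tau = np.empty(N_VGATES)
        gate_rates(v, variant, inf, tau)
        for g in range(N_VGATES):
            s[g] = inf[g] + (s[g] - inf[g]) * np.exp(-dt / tau[g])

    css_sq = 1.0 + (s[14] / 0.05) ** 2
    fcass_inf = 0.6 / css_sq + 0.4
    tau_fcass = 80.0 / css_sq + 2.0
    s[11] = fcass_inf + (s[11] - fcass_inf) * np.exp(-dt / tau_fcass)

    # rbar obeys drbar/dt = k4*(1 - rbar) - k2*cass*rbar: exact with frozen cass
    krb = k2 * s[14] + K4_REL
    rb_inf = K4_REL / krb
    s[12] = rb_inf + (s[12] - rb_inf) * np.exp(-dt * krb)

    # ----- forward Euler for concentrations -----
    cfac = CAPACITANCE / (2.0 * V_C * FARADAY)
    bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / (s[13] + K_BUF_C) ** 2)
    dcai = bufc * (
        (ileak - iup) * V_SR / V_C + ixfer - (ibca + ipca - 2.0 * inaca) * cfac
    )
    bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (s[15] + K_BUF_SR) ** 2)
    dcasr = bufsr * (iup - irel - ileak)
    bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (s[14] + K_BUF_SS) ** 2)
    dcass = bufss * (
        -ixfer * V_C / V_SS
        + irel * V_SR / V_SS
        - ical * CAPACITANCE / (2.0 * V_SS * FARADAY)
    )
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (V_C * FARADAY)
    # istim carries charge as a K+ current, as in the published formulation
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + isac - istim) * (
        CAPACITANCE / (V_C * FARADAY)
    )
    s[13] += dt * dcai
    s[14] += dt * dcass
    s[15] += dt * dcasr
    s[16] += dt * dnai
    s[17] += dt * dki

    return v + dt * (istim - iion)


@njit(cache=True)
def step_cells(V, S, dt, nsub, istim, gsac_seq, sac_mask, esac, gks_eff, gto,
               gkr, variant, use_table, v0, dvinv, inf_tab, exp_tab):
    """Advance every cell by ``nsub`` reaction substeps of size ``dt``.

    ``istim`` is a per-cell depolarizing current (uA/uF) held constant over
    the substeps; ``gsac_seq`` gives the SAC conductance at each substep,
    applied to cells where ``sac_mask`` is nonzero.
    """
    n = V.shape[0]
    for i in range(n):
        v = V[i]
        s = S[i]
        for k in range(nsub):
            g = gsac_seq[k] if sac_mask[i] else 0.0
            v = _step_one(v, s, dt, istim[i], g, esac, gks_eff[i], gto[i],
                          gkr[i], variant, use_table, v0, dvinv,
                          inf_tab, exp_tab)
        V[i] = v


_EMPTY_TAB = np.zeros((2, N_VGATES))


def initial_state(n=1):
    """Published resting state broadcast to ``n`` cells: (V, S) arrays."""
    V = np.full(n, V_REST_INIT)
    S = np.tile(STATE_INIT, (n, 1))
    return V, S
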