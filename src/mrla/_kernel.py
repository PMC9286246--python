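"""Numerical kernel for the closed-loop circulation model.

Flat-array layout so the whole right-hand side can be jit-compiled with
numba (pure-python fallback if numba is unavailable). All pressures are in
mmHg, volumes in mL, flows in mL/s, areas in cm2, stresses in kPa, times in
seconds.

State vector (length 17):
    0..3   cavity volumes          V_la, V_ra, V_lv, V_rv
    4..7   vessel volumes          V_sysart, V_sysven, V_pulmart, V_pulmven
    8..11  valve flows             q_mv, q_av, q_tv, q_pv
    12..15 valve opening states    z_mv, z_av, z_tv, z_pv   (0 closed .. 1 open)
    16     unused (reserved; the LV free-wall/septum area split is solved
           algebraically by tension balance)

Parameter vector: see index constants below. Patch order is
LA, RA, LVFW, LVSW, RV; valve order MV, AV, TV, PV; vessel order
sysart, sysven, pulmart, pulmven.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# ---------------------------------------------------------------- indices
NSTATE = 17

IV_LA, IV_RA, IV_LV, IV_RV = 0, 1, 2, 3
IV_SA, IV_SV, IV_PA, IV_PV = 4, 5, 6, 7
IQ_MV, IQ_AV, IQ_TV, IQ_PV = 8, 9, 10, 11
IZ_MV, IZ_AV, IZ_TV, IZ_PV = 12, 13, 14, 15
IX_FW = 16

# params
I_TCYC = 0
PATCH0 = 1          # 5 patches x 14 params
NPPATCH = 14
# per patch: VW, AREF, ONSET, TWITCH, SACT, SPAS, KPAS, FSS, SCOL, KCOL,
# LCOL, CCOMP, TRISE, GMAX
(P_VW, P_AREF, P_ONSET, P_TWITCH, P_SACT, P_SPAS, P_KPAS, P_FSS,
 P_SCOL, P_KCOL, P_LCOL, P_CCOMP, P_TRISE, P_GMAX) = range(14)
PATCH_LA, PATCH_RA, PATCH_LVFW, PATCH_LVSW, PATCH_RV = range(5)

VALVE0 = PATCH0 + 5 * NPPATCH      # 4 valves x 5 params
NPVALVE = 5
# per valve: AOPEN, ALEAK, LLEN, KV, RLIN (series viscous/characteristic
# resistance; for the aortic valve this is the arterial characteristic
# impedance)
V_AOPEN, V_ALEAK, V_LLEN, V_KV, V_RLIN = range(5)

VESSEL0 = VALVE0 + 4 * NPVALVE     # 4 vessels x 2 params
NPVESSEL = 2
# per vessel: CAP, VUN

I_RSYS = VESSEL0 + 4 * NPVESSEL
I_RPULM = I_RSYS + 1
I_RVENRA = I_RSYS + 2
I_RVENLA = I_RSYS + 3
I_BERN = I_RSYS + 4                # Bernoulli coefficient, mmHg/(cm/s)^2
NPARAM = I_BERN + 1

FOUR_PI = 4.0 * math.pi
KPA_TO_MMHG = 7.50062
# rho/2 / 1333.22: dynamic pressure of blood (rho = 1.05 g/mL) in mmHg
BERNOULLI = 0.5 * 1.05 / 1333.22
# rho/1333.22: inertance per (length/area) in mmHg.s^2/mL
INERT_COEF = 1.05 / 1333.22
RATE_MAX = 800.0  # cap on valve opening/closing rate, 1/s  (~1-3 ms transition)


@njit(cache=True)
def _stress(t, lam, onset, twitch, sact, spas, kpas, fss,
            scol, kcol, lcol, ccomp, trise, gmax, tcyc):
    """Total fiber stress (kPa) of a patch at cycle time t and stretch lam.

    The twitch is a rise-plateau-fall envelope: sine-squared ramps of width
    trise*twitch on both flanks; trise = 0.5 recovers the pure raised
    cosine (no plateau)."""
    tau = (t - onset) % tcyc
    s = 0.0
    if tau < twitch:
        tr = trise * twitch
        if tau < tr:
            w = math.sin(0.5 * math.pi * tau / tr)
            s = w * w
        elif tau > twitch - tr:
            w = math.sin(0.5 * math.pi * (twitch - tau) / tr)
            s = w * w
        else:
            s = 1.0
    # length dependence: linear ascending limb with a plateau at gmax
    # (the Frank-Starling curve saturates near optimal fiber length)
    g = 1.0 + fss * (lam - 1.0)
    if g < 0.0:
        g = 0.0
    elif g > gmax:
        g = gmax
    sig_a = sact * g * s
    # passive branch: exponential in extension; linear compressive
    # resistance below slack (keeps contracting chambers from collapsing
    # and the tension balance well-posed)
    if lam >= 1.0:
        sig_p = spas * math.expm1(kpas * (lam - 1.0))
    else:
        # compression slope can exceed the extension slope at slack
        # (incompressible wall buckling); C0 at lam=1
        sig_p = spas * kpas * ccomp * (lam - 1.0)
    # collagen recruitment: a much steeper exponential engaging beyond the
    # slack stretch lcol (biphasic passive curve of atrial myocardium)
    if scol > 0.0 and lam > lcol:
        sig_p += scol * math.expm1(kcol * (lam - lcol))
    return sig_a + sig_p


@njit(cache=True)
def _single_wall(t, vol, P, base, tcyc):
    """Pressure (mmHg) and midwall area (cm2) of a one-patch spherical chamber."""
    vw = P[base + P_VW]
    vm = vol + 0.5 * vw
    r = (3.0 * vm / FOUR_PI) ** (1.0 / 3.0)
    area = FOUR_PI * r * r
    lam = math.sqrt(area / P[base + P_AREF])
    sig = _stress(t, lam, P[base + P_ONSET], P[base + P_TWITCH],
                  P[base + P_SACT], P[base + P_SPAS], P[base + P_KPAS],
                  P[base + P_FSS], P[base + P_SCOL], P[base + P_KCOL],
                  P[base + P_LCOL], P[base + P_CCOMP], P[base + P_TRISE],
                  P[base + P_GMAX], tcyc)
    h = vw / area
    p = 2.0 * sig * h / r * KPA_TO_MMHG
    return p, area


@njit(cache=True)
def _patch_tension(t, a_patch, base, P, tcyc):
    """Wall tension sigma*h (kPa.cm) of a patch covering midwall area a."""
    lam = math.sqrt(a_patch / P[base + P_AREF])
    sig = _stress(t, lam, P[base + P_ONSET], P[base + P_TWITCH],
                  P[base + P_SACT], P[base + P_SPAS], P[base + P_KPAS],
                  P[base + P_FSS], P[base + P_SCOL], P[base + P_KCOL],
                  P[base + P_LCOL], P[base + P_CCOMP], P[base + P_TRISE],
                  P[base + P_GMAX], tcyc)
    return sig * P[base + P_VW] / a_patch


@njit(cache=True)
def _lv_wall(t, vol, P, tcyc):
    """Two-patch (free wall + septum) LV sharing one spherical cavity.

    The patches are mechanically in series along the wall: they split the
    total midwall area such that their wall tensions (sigma*h) are equal.
    The tension-balance root is solved by bisection (the imbalance is
    monotone in the split), so dyssynchronous activation stretches the
    late-activated patch at the expense of the early one.
    Returns (p, area_total, a_fw, a_sw).
    """
    bf = PATCH0 + PATCH_LVFW * NPPATCH
    bs = PATCH0 + PATCH_LVSW * NPPATCH
    vm = vol + 0.5 * (P[bf + P_VW] + P[bs + P_VW])
    r = (3.0 * vm / FOUR_PI) ** (1.0 / 3.0)
    area = FOUR_PI * r * r
    lo = 0.05 * area
    hi = 0.95 * area
    a_fw = area * P[bf + P_AREF] / (P[bf + P_AREF] + P[bs + P_AREF])
    for _ in range(48):
        f = _patch_tension(t, a_fw, bf, P, tcyc) \
            - _patch_tension(t, area - a_fw, bs, P, tcyc)
        if f > 0.0:
            hi = a_fw
        else:
            lo = a_fw
        a_fw = 0.5 * (lo + hi)
        if hi - lo < 1.0e-10 * area:
            break
    a_sw = area - a_fw
    ten = _patch_tension(t, a_fw, bf, P, tcyc)
    p = 2.0 * ten / r * KPA_TO_MMHG
    return p, area, a_fw, a_sw


@njit(cache=True)
def _valve_rhs(pup, pdn, q, z, aopen, aleak, llen, kv, bern, rlin):
    """dq/dt and dz/dt for one valve (orifice + inertance + opening dynamics)."""
    dp = pup - pdn
    aeff = aleak + (aopen - aleak) * z
    amin = 0.002 * aopen
    if aeff < amin:
        aeff = amin
    inert = INERT_COEF * llen / aeff
    v = q / aeff
    dq = (dp - bern * v * abs(v) - rlin * q) / inert
    if dp >= 0.0:
        rate = kv * dp
        if rate > RATE_MAX:
            rate = RATE_MAX
        dz = rate * (1.0 - z)
    else:
        rate = -kv * dp
        if rate > RATE_MAX:
            rate = RATE_MAX
        dz = -rate * z
    return dq, dz


# aux layout (observables recorded alongside the state)
NAUX = 17
A_PLA, A_PRA, A_PLV, A_PRV = 0, 1, 2, 3
A_PSA, A_PSV, A_PPA, A_PPV = 4, 5, 6, 7
A_ALA, A_ARA, A_AFW, A_ASW, A_ARV = 8, 9, 10, 11, 12
A_QVENLA, A_QVENRA, A_QSYS, A_QPULM = 13, 14, 15, 16


@njit(cache=True)
def _rhs(t, y, P, dy, aux):
    tcyc = P[I_TCYC]
    p_la, a_la = _single_wall(t, y[IV_LA], P, PATCH0 + PATCH_LA * NPPATCH, tcyc)
    p_ra, a_ra = _single_wall(t, y[IV_RA], P, PATCH0 + PATCH_RA * NPPATCH, tcyc)
    p_lv, _a_lv, a_fw, a_sw = _lv_wall(t, y[IV_LV], P, tcyc)
    p_rv, a_rv = _single_wall(t, y[IV_RV], P, PATCH0 + PATCH_RV * NPPATCH, tcyc)

    p_sa = (y[IV_SA] - P[VESSEL0 + 1]) / P[VESSEL0 + 0]
    p_sv = (y[IV_SV] - P[VESSEL0 + 3]) / P[VESSEL0 + 2]
    p_pa = (y[IV_PA] - P[VESSEL0 + 5]) / P[VESSEL0 + 4]
    p_pv = (y[IV_PV] - P[VESSEL0 + 7]) / P[VESSEL0 + 6]

    bern = P[I_BERN]
    b = VALVE0
    dq_mv, dz_mv = _valve_rhs(p_la, p_lv, y[IQ_MV], y[IZ_MV],
                              P[b], P[b + 1], P[b + 2], P[b + 3], bern, P[b + 4])
    b = VALVE0 + NPVALVE
    dq_av, dz_av = _valve_rhs(p_lv, p_sa, y[IQ_AV], y[IZ_AV],
                              P[b], P[b + 1], P[b + 2], P[b + 3], bern, P[b + 4])
    b = VALVE0 + 2 * NPVALVE
    dq_tv, dz_tv = _valve_rhs(p_ra, p_rv, y[IQ_TV], y[IZ_TV],
                              P[b], P[b + 1], P[b + 2], P[b + 3], bern, P[b + 4])
    b = VALVE0 + 3 * NPVALVE
    dq_pv, dz_pv = _valve_rhs(p_rv, p_pa, y[IQ_PV], y[IZ_PV],
                              P[b], P[b + 1], P[b + 2], P[b + 3], bern, P[b + 4])

    q_sys = (p_sa - p_sv) / P[I_RSYS]
    q_venra = (p_sv - p_ra) / P[I_RVENRA]
    q_pulm = (p_pa - p_pv) / P[I_RPULM]
    q_venla = (p_pv - p_la) / P[I_RVENLA]

    dy[IV_LA] = q_venla - y[IQ_MV]
    dy[IV_RA] = q_venra - y[IQ_TV]
    dy[IV_LV] = y[IQ_MV] - y[IQ_AV]
    dy[IV_RV] = y[IQ_TV] - y[IQ_PV]
    dy[IV_SA] = y[IQ_AV] - q_sys
    dy[IV_SV] = q_sys - q_venra
    dy[IV_PA] = y[IQ_PV] - q_pulm
    dy[IV_PV] = q_pulm - q_venla
    dy[IQ_MV] = dq_mv
    dy[IQ_AV] = dq_av
    dy[IQ_TV] = dq_tv
    dy[IQ_PV] = dq_pv
    dy[IZ_MV] = dz_mv
    dy[IZ_AV] = dz_av
    dy[IZ_TV] = dz_tv
    dy[IZ_PV] = dz_pv
    dy[IX_FW] = 0.0   # split is algebraic (tension balance); state unused

    aux[A_PLA] = p_la
    aux[A_PRA] = p_ra
    aux[A_PLV] = p_lv
    aux[A_PRV] = p_rv
    aux[A_PSA] = p_sa
    aux[A_PSV] = p_sv
    aux[A_PPA] = p_pa
    aux[A_PPV] = p_pv
    aux[A_ALA] = a_la
    aux[A_ARA] = a_ra
    aux[A_AFW] = a_fw
    aux[A_ASW] = a_sw
    aux[A_ARV] = a_rv
    aux[A_QVENLA] = q_venla
    aux[A_QVENRA] = q_venra
    aux[A_QSYS] = q_sys
    aux[A_QPULM] = q_pulm


@njit(cache=True)
def integrate_beat(y, P, nst, dt, yout, auxout, record):
    """Integrate one cardiac cycle in place with fixed-step RK4.

    Returns (status, chamber, step): status 0 = ok, 1 = negative cavity
    volume in chamber index `chamber` at step `step`.
    """
    k1 = np.empty(NSTATE)
    k2 = np.empty(NSTATE)
    k3 = np.empty(NSTATE)
    k4 = np.empty(NSTATE)
    yt = np.empty(NSTATE)
    aux = np.empty(NAUX)
    t = 0.0
    if record:
        _rhs(t, y, P, k1, aux)
        for j in range(NSTATE):
            yout[0, j] = y[j]
        for j in range(NAUX):
            auxout[0, j] = aux[j]
    for i in range(nst):
        _rhs(t, y, P, k1, aux)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(t + 0.5 * dt, yt, P, k2, aux)
        for j in range(NSTATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(t + 0.5 * dt, yt, P, k3, aux)
        for j in range(NSTATE):
            yt[j] = y[j] + dt * k3[j]
        _rhs(t + dt, yt, P, k4, aux)
        for j in range(NSTATE):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        # valve housekeeping: opening state in [0,1]; a valve without a leak
        # orifice cannot carry backward flow (exact zero-leak identity)
        for v in range(4):
            iz = IZ_MV + v
            if y[iz] < 0.0:
                y[iz] = 0.0
            elif y[iz] > 1.0:
                y[iz] = 1.0
            if P[VALVE0 + v * NPVALVE + V_ALEAK] == 0.0 and y[IQ_MV + v] < 0.0:
                y[IQ_MV + v] = 0.0
        for c in range(4):
            if y[c] <= 0.0:
                return 1, c, i
        t += dt
        if record:
            _rhs(t, y, P, k1, aux)
            for j in range(NSTATE):
                yout[i + 1, j] = y[j]
            for j in range(NAUX):
                auxout[i + 1, j] = aux[j]
    return 0, -1, nst
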