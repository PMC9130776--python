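"""Compiled core of the closed-loop simulator.

State layout (ODE vector y):
    0 V_LV   1 V_RV   2 V_LA   3 V_RA        cavity volumes (ml)
    4 V_SyArt 5 V_SyVen 6 V_PuArt 7 V_PuVen  vessel volumes (ml)
    8 q_Mi   9 q_Ao  10 q_Tr  11 q_Pu        valve flows (ml/s)
    12+i     Lsi of patch i (um)

Walls are indexed 0 LV free wall, 1 septum, 2 RV free wall, 3 LA, 4 RA.
The three ventricular walls form a three-segment (TriSeg) force balance:
spherical caps sharing a junction ring of radius ym, with the septal cap
volume VS and ym solved quasi-statically each evaluation so the axial and
radial tension components balance.  Within a wall, patches share one
tension; each patch contributes a linearized area-tension relation
Am_i(T) = Am0_i + dAdT_i * T derived from its sarcomere stiffness, so a
wall's tension follows algebraically from its geometric midwall area
(MultiPatch construction).  Atrial walls are single spherical shells.

Cavity pressure uses the thick-shell one-fiber relation
p = 2 * Tm * Cm with the wall tension Tm = sigma * Vw / (2 Am) * zeta(z),
zeta = 1 + z^2/3 + z^4/5, z = 3 Cm Vw / (2 Am).

Units: volume ml, area cm^2, curvature 1/cm, stress kPa, tension kPa*cm,
pressure mmHg, flow ml/s, time s, sarcomere length um.
"""

import math

import numpy as np
from numba import njit

from .sarcomere import _contractility
from .compartments import _split_equal_stress

KPA_MMHG = 7.5006157584566

# global-parameter vector indices
GP_TC = 0; GP_DT = 1
GP_RSYS = 2; GP_RPULM = 3; GP_RSV = 4; GP_RPV = 5
GP_CSA = 6; GP_CSV = 7; GP_CPA = 8; GP_CPV = 9
GP_V0SA = 10; GP_V0SV = 11; GP_V0PA = 12; GP_V0PV = 13
GP_LVALVE = 14; GP_BMI = 15; GP_BAO = 16; GP_BTR = 17; GP_BPU = 18
GP_TACTV = 19; GP_TACTA = 20; GP_LSREF = 21; GP_RLVALVE = 22; GP_ERRTOL = 23
NGP = 24

# patch-parameter columns
PP_VW = 0; PP_AMREF = 1; PP_NCVF = 2; PP_SFACT = 3; PP_SFPAS = 4
PP_LS0PAS = 5; PP_KECM = 6; PP_K1TIT = 7; PP_K2TIT = 8; PP_LSI0 = 9
PP_LSEISO = 10; PP_VMAX = 11; PP_CD = 12; PP_ACTOFF = 13
PP_SFPASNC = 14; PP_LS0PASNC = 15; PP_KECMNC = 16; PP_CREST = 17
NPP = 18

# state indices
IY_VLV = 0; IY_VRV = 1; IY_VLA = 2; IY_VRA = 3
IY_VSA = 4; IY_VSV = 5; IY_VPA = 6; IY_VPV = 7
IY_QMI = 8; IY_QAO = 9; IY_QTR = 10; IY_QPU = 11
IY_LSI0 = 12

# cache layout
IC_VS = 0; IC_YM = 1; IC_XM = 2            # 2,3,4 xm of walls 0..2
IC_CM = 5                                   # 5..9 Cm of walls 0..4
IC_PATCH = 10                               # 10+2i Ls_i, 11+2i LsNC_i

# aux layout
IA_PLV = 0; IA_PRV = 1; IA_PLA = 2; IA_PRA = 3
IA_PSA = 4; IA_PSV = 5; IA_PPA = 6; IA_PPV = 7
IA_TW = 8                                   # 8..12 wall tensions
IA_VS = 13; IA_YM = 14; IA_NIT = 15
NAUXG = 16                                  # then 4 per patch: Ls, LsC, LsNC, sigma

_MIN_STIFF = 0.2   # kPa/um floor used in the area-tension linearization


@njit(cache=True)
def _solve_xm(V, ym, x0):
    """Solve (pi/6) x (x^2 + 3 ym^2) = V for the cap height x (monotone)."""
    x = x0
    c = math.pi / 6.0
    for _ in range(40):
        g = c * x * (x * x + 3.0 * ym * ym) - V
        gp = c * (3.0 * x * x + 3.0 * ym * ym)
        dx = g / gp
        x -= dx
        if abs(dx) < 1e-12 * (1.0 + abs(x)):
            break
    return x


@njit(cache=True)
def _triseg_residual(VS, ym, VLV, VRV, VwL, VwS, VwR,
                     sAm0, sDADT, xm_ws, out):
    """Tension balance residuals at the TriSeg junction ring.

    out: [Rx, Ry, TL, TS, TR, CmL, CmS, CmR, xmL, xmS, xmR, AmL, AmS, AmR]
    """
    VmL = -(VLV + 0.5 * VwL + 0.5 * VwS) + VS
    VmS = VS
    VmR = VRV + 0.5 * VwR + 0.5 * VwS + VS
    rx = 0.0
    ry = 0.0
    for w in range(3):
        if w == 0:
            Vm = VmL
        elif w == 1:
            Vm = VmS
        else:
            Vm = VmR
        xm = _solve_xm(Vm, ym, xm_ws[w])
        r2 = xm * xm + ym * ym
        Am = math.pi * r2
        Cm = 2.0 * xm / r2
        T = (Am - sAm0[w]) / sDADT[w]
        sinr = 2.0 * xm * ym / r2
        cosr = (ym * ym - xm * xm) / r2
        rx += T * sinr
        ry += T * cosr
        out[2 + w] = T
        out[5 + w] = Cm
        out[8 + w] = xm
        out[11 + w] = Am
    out[0] = rx
    out[1] = ry
    return rx, ry


@njit(cache=True)
def _deriv(t, y, gp, PP, pwall, VwWall, cache, dy, aux):
    n_patch = PP.shape[0]
    tc = gp[GP_TC]
    LsRef = gp[GP_LSREF]

    sAm0 = np.zeros(5)
    sDADT = np.zeros(5)
    am0_i = np.empty(n_patch)
    dadt_i = np.empty(n_patch)
    C_i = np.empty(n_patch)

    # --- patch linearization at cached composite length -------------------
    for i in range(n_patch):
        w = pwall[i]
        act = gp[GP_TACTV] if w < 3 else gp[GP_TACTA]
        act += PP[i, PP_ACTOFF]
        ta = (t - act) % tc
        Lsi = y[IY_LSI0 + i]
        C = _contractility(ta, Lsi, PP[i, PP_CD], PP[i, PP_CREST])
        C_i[i] = C
        Ls = cache[IC_PATCH + 2 * i]
        LsNCg = cache[IC_PATCH + 2 * i + 1]
        LsC, LsNC, sig, dsig = _split_equal_stress(
            Ls, Lsi, C, PP[i, PP_NCVF],
            PP[i, PP_SFACT], PP[i, PP_SFPAS], PP[i, PP_LS0PAS],
            PP[i, PP_KECM], PP[i, PP_K1TIT], PP[i, PP_K2TIT],
            PP[i, PP_LSI0], PP[i, PP_LSEISO],
            PP[i, PP_SFPASNC], PP[i, PP_LS0PASNC], PP[i, PP_KECMNC],
            LsNCg)
        cache[IC_PATCH + 2 * i + 1] = LsNC
        lam = Ls / LsRef
        Am = PP[i, PP_AMREF] * lam * lam
        Cmw = cache[IC_CM + w]
        z = 1.5 * Cmw * PP[i, PP_VW] / Am
        zeta = 1.0 + z * z / 3.0 + z * z * z * z / 5.0
        T0 = sig * PP[i, PP_VW] / (2.0 * Am) * zeta
        dTdLs = PP[i, PP_VW] * zeta / (2.0 * Am) * max(dsig, _MIN_STIFF)
        dadt = (2.0 * Am / Ls) / dTdLs
        am0 = Am - dadt * T0
        am0_i[i] = am0
        dadt_i[i] = dadt
        sAm0[w] += am0
        sDADT[w] += dadt

    # --- atria: single spherical shells -----------------------------------
    for w in range(3, 5):
        Vcav = y[IY_VLA] if w == 3 else y[IY_VRA]
        Vm = Vcav + 0.5 * VwWall[w]
        r = (0.75 * Vm / math.pi) ** (1.0 / 3.0)
        Am = 4.0 * math.pi * r * r
        Cm = 1.0 / r
        T = (Am - sAm0[w]) / sDADT[w]
        p = 2.0 * T * Cm * KPA_MMHG
        cache[IC_CM + w] = Cm
        aux[IA_TW + w] = T
        if w == 3:
            aux[IA_PLA] = p
        else:
            aux[IA_PRA] = p

    # --- TriSeg force balance (Newton on VS, ym) --------------------------
    VS = cache[IC_VS]
    ym = cache[IC_YM]
    xm_ws = cache[IC_XM:IC_XM + 3].copy()
    res = np.empty(14)
    resa = np.empty(14)
    resb = np.empty(14)
    VLV = y[IY_VLV]
    VRV = y[IY_VRV]
    hV = 1e-3
    hy = 1e-4
    err = 0.0
    for it in range(40):
        rx, ry = _triseg_residual(VS, ym, VLV, VRV, VwWall[0], VwWall[1],
                                  VwWall[2], sAm0, sDADT, xm_ws, res)
        Tscale = 1.0 + abs(res[2]) + abs(res[3]) + abs(res[4])
        err = math.sqrt(rx * rx + ry * ry)
        if err < 1e-7 * Tscale:
            break
        rxa, rya = _triseg_residual(VS + hV, ym, VLV, VRV, VwWall[0],
                                    VwWall[1], VwWall[2], sAm0, sDADT,
                                    xm_ws, resa)
        rxb, ryb = _triseg_residual(VS, ym + hy, VLV, VRV, VwWall[0],
                                    VwWall[1], VwWall[2], sAm0, sDADT,
                                    xm_ws, resb)
        j11 = (rxa - rx) / hV
        j21 = (rya - ry) / hV
        j12 = (rxb - rx) / hy
        j22 = (ryb - ry) / hy
        det = j11 * j22 - j12 * j21
        if abs(det) < 1e-14:
            break
        dVS = (-rx * j22 + ry * j12) / det
        dym = (-j11 * ry + j21 * rx) / det
        if dVS > 25.0:
            dVS = 25.0
        elif dVS < -25.0:
            dVS = -25.0
        if dym > 0.4:
            dym = 0.4
        elif dym < -0.4:
            dym = -0.4
        VS += dVS
        ym += dym
        if ym < 0.5:
            ym = 0.5
    cache[IC_VS] = VS
    cache[IC_YM] = ym
    for w in range(3):
        cache[IC_XM + w] = res[8 + w]
        cache[IC_CM + w] = res[5 + w]
    TL = res[2]
    TR = res[4]
    CmL = res[5]
    CmR = res[7]
    pLV = -2.0 * TL * CmL * KPA_MMHG
    pRV = 2.0 * TR * CmR * KPA_MMHG
    aux[IA_PLV] = pLV
    aux[IA_PRV] = pRV
    aux[IA_TW + 0] = TL
    aux[IA_TW + 1] = res[3]
    aux[IA_TW + 2] = TR
    aux[IA_VS] = VS
    aux[IA_YM] = ym
    aux[IA_NIT] = it

    # --- patch state update at solved tension -----------------------------
    for i in range(n_patch):
        w = pwall[i]
        T = aux[IA_TW + w]
        Am_new = am0_i[i] + dadt_i[i] * T
        amr = PP[i, PP_AMREF]
        if Am_new < 0.05 * amr:
            Am_new = 0.05 * amr
        Ls_new = LsRef * math.sqrt(Am_new / amr)
        cache[IC_PATCH + 2 * i] = Ls_new
        Lsi = y[IY_LSI0 + i]
        LsC, LsNC, sig, dsig = _split_equal_stress(
            Ls_new, Lsi, C_i[i], PP[i, PP_NCVF],
            PP[i, PP_SFACT], PP[i, PP_SFPAS], PP[i, PP_LS0PAS],
            PP[i, PP_KECM], PP[i, PP_K1TIT], PP[i, PP_K2TIT],
            PP[i, PP_LSI0], PP[i, PP_LSEISO],
            PP[i, PP_SFPASNC], PP[i, PP_LS0PASNC], PP[i, PP_KECMNC],
            cache[IC_PATCH + 2 * i + 1])
        cache[IC_PATCH + 2 * i + 1] = LsNC
        aux[NAUXG + 4 * i + 0] = Ls_new
        aux[NAUXG + 4 * i + 1] = LsC
        aux[NAUXG + 4 * i + 2] = LsNC
        aux[NAUXG + 4 * i + 3] = sig
        if PP[i, PP_NCVF] >= 1.0:
            dy[IY_LSI0 + i] = 0.0
        else:
            dy[IY_LSI0 + i] = ((LsC - Lsi) / PP[i, PP_LSEISO] - 1.0) \
                * PP[i, PP_VMAX]

    # --- vessels ----------------------------------------------------------
    pSA = (y[IY_VSA] - gp[GP_V0SA]) / gp[GP_CSA]
    pSV = (y[IY_VSV] - gp[GP_V0SV]) / gp[GP_CSV]
    pPA = (y[IY_VPA] - gp[GP_V0PA]) / gp[GP_CPA]
    pPV = (y[IY_VPV] - gp[GP_V0PV]) / gp[GP_CPV]
    aux[IA_PSA] = pSA
    aux[IA_PSV] = pSV
    aux[IA_PPA] = pPA
    aux[IA_PPV] = pPV
    pLA = aux[IA_PLA]
    pRA = aux[IA_PRA]

    # --- flows ------------------------------------------------------------
    qSys = (pSA - pSV) / gp[GP_RSYS]
    qPul = (pPA - pPV) / gp[GP_RPULM]
    qSyRet = (pSV - pRA) / gp[GP_RSV]
    qPuRet = (pPV - pLA) / gp[GP_RPV]

    L = gp[GP_LVALVE]
    Rl = gp[GP_RLVALVE]
    # mitral, aortic, tricuspid, pulmonary
    for k in range(4):
        q = y[IY_QMI + k]
        if q < 0.0:
            q = 0.0
        if k == 0:
            dp = pLA - pLV
            B = gp[GP_BMI]
        elif k == 1:
            dp = pLV - pSA
            B = gp[GP_BAO]
        elif k == 2:
            dp = pRA - pRV
            B = gp[GP_BTR]
        else:
            dp = pRV - pPA
            B = gp[GP_BPU]
        if q > 0.0 or dp > 0.0:
            dy[IY_QMI + k] = (dp - B * q * q - Rl * q) / L
        else:
            dy[IY_QMI + k] = 0.0

    qMi = max(y[IY_QMI], 0.0)
    qAo = max(y[IY_QAO], 0.0)
    qTr = max(y[IY_QTR], 0.0)
    qPu = max(y[IY_QPU], 0.0)

    dy[IY_VLV] = qMi - qAo
    dy[IY_VRV] = qTr - qPu
    dy[IY_VLA] = qPuRet - qMi
    dy[IY_VRA] = qSyRet - qTr
    dy[IY_VSA] = qAo - qSys
    dy[IY_VSV] = qSys - qSyRet
    dy[IY_VPA] = qPu - qPul
    dy[IY_VPV] = qPul - qPuRet


@njit(cache=True)
def _clamp(y):
    for k in range(4):
        if y[IY_QMI + k] < 0.0:
            y[IY_QMI + k] = 0.0
    for k in range(8):
        if y[k] < 0.5:
            y[k] = 0.5


@njit(cache=True)
def _run_steps(t0, n_steps, y, gp, PP, pwall, VwWall, cache,
               rec_y, rec_aux, record, max_evals):
    """Advance n_steps grid steps of size gp[GP_DT] with Heun substeps.

    Each grid step is attempted with an increasing number of substeps until
    the embedded (Euler vs Heun) local error estimate passes gp[GP_ERRTOL].
    Records y and aux on the fixed output grid when record is True.

    Returns (t_end, status): status 1 means the derivative-evaluation
    budget ``max_evals`` was exhausted (pathological stiffness) and the
    run was aborted early; callers should treat the state as invalid.
    """
    ny = y.size
    n_patch = PP.shape[0]
    naux = NAUXG + 4 * n_patch
    dy1 = np.empty(ny)
    dy2 = np.empty(ny)
    aux = np.empty(naux)
    y1 = np.empty(ny)
    dt = gp[GP_DT]
    tol = gp[GP_ERRTOL]
    # error scales per state
    scale = np.empty(ny)
    for k in range(8):
        scale[k] = 100.0
    for k in range(8, 12):
        scale[k] = 2000.0
    for k in range(12, ny):
        scale[k] = 2.0

    y_save = np.empty(ny)
    cache_save = np.empty(cache.size)
    dy0 = np.empty(ny)
    n_sub = 1          # persists across steps; stiffness is usually local
    n_evals = 0
    psa_sum = 0.0      # for between-beat regulation without a full record
    sv_int = 0.0

    for step in range(n_steps):
        if n_evals > max_evals:
            return t0 + step * dt, 1, 0.0, 0.0
        t = t0 + step * dt
        # derivative at the grid point doubles as the recording sample and
        # as the first substep of the first attempt
        _deriv(t, y, gp, PP, pwall, VwWall, cache, dy0, aux)
        n_evals += 1
        psa_sum += aux[IA_PSA]
        q = y[IY_QAO]
        if q > 0.0:
            sv_int += q * dt
        if record:
            for k in range(ny):
                rec_y[step, k] = y[k]
            for k in range(naux):
                rec_aux[step, k] = aux[k]
        for k in range(ny):
            y_save[k] = y[k]
        for k in range(cache.size):
            cache_save[k] = cache[k]
        if n_sub > 1:
            n_sub //= 2
        for attempt in range(6):
            h = dt / n_sub
            ok = True
            for s in range(n_sub):
                ts = t + s * h
                if s == 0:
                    for k in range(ny):
                        dy1[k] = dy0[k]
                else:
                    _deriv(ts, y, gp, PP, pwall, VwWall, cache, dy1, aux)
                    n_evals += 1
                for k in range(ny):
                    y1[k] = y[k] + h * dy1[k]
                _clamp(y1)
                _deriv(ts + h, y1, gp, PP, pwall, VwWall, cache, dy2, aux)
                n_evals += 1
                emax = 0.0
                for k in range(ny):
                    e = 0.5 * h * abs(dy2[k] - dy1[k]) / scale[k]
                    if e > emax:
                        emax = e
                if emax > tol and attempt < 5:
                    ok = False
                    break
                for k in range(ny):
                    y[k] = y[k] + 0.5 * h * (dy1[k] + dy2[k])
                _clamp(y)
            if ok:
                break
            # restore and retry the whole grid step with smaller substeps
            for k in range(ny):
                y[k] = y_save[k]
            for k in range(cache.size):
                cache[k] = cache_save[k]
            n_sub *= 2
    tend = t0 + n_steps * dt
    _deriv(tend, y, gp, PP, pwall, VwWall, cache, dy1, aux)
    if record:
        for k in range(ny):
            rec_y[n_steps, k] = y[k]
        for k in range(naux):
            rec_aux[n_steps, k] = aux[k]
    return tend, 0, psa_sum / n_steps, sv_int
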