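"""Numba kernel for the double-cable axon time integration.

State per compartment: intracellular potential Vi and periaxonal potential
Vp (both mV, ground-referenced).  The axolemma separates Vi from Vp; the
myelin sheath separates Vp from the imposed extracellular potential Ve.
Nodes of Ranvier carry no myelin: their sheath conductance is set huge so
Vp is pinned to Ve and the node reduces to a single cable.

Each step: gating variables advance by exponential (Rush-Larsen) updates
on a staggered (half-step) grid using rates at the current membrane
potential, then the coupled linear system in (Vi, Vp) is advanced by a
Crank-Nicolson (theta = 1/2) step with the ionic conductances evaluated at
the gate half-step and the driving potential at the voltage midpoint; with
gates frozen the ionic currents are linear in V, so the voltage update
needs one linear solve and the staggered scheme is second-order accurate
in dt (the node sheath short, an algebraic constraint, is kept fully
implicit).  The system matrix is
pentadiagonal under interleaved ordering (Vi_0, Vp_0, Vi_1, ...) and is
solved by banded elimination without pivoting (symmetric positive
definite: diagonals are sums of positive conductances and
capacitance/dt terms).  Entries that depend only on geometry and the step
size are precomputed and refreshed only when dt changes (the time grid is
piecewise-uniform), so the per-step work is the gate update at excitable
compartments plus one banded solve.

Compartment type codes: 0 node, 1 MYSA, 2 FLUT, 3 STIN (types 0-2 carry
voltage-gated channels).  Units: mV, ms, mS, uF, uA.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_cable", "steady_gates"]


@njit(cache=True, inline="always")
def _vtrap(x: float, k: float) -> float:
    # x / (1 - exp(-x/k)), stable near x = 0
    if abs(x / k) < 1e-6:
        return k * (1.0 + x / (2.0 * k))
    return x / (1.0 - np.exp(-x / k))


@njit(cache=True, inline="always")
def _rates_na(v, q10_1, q10_2):
    """Fast/persistent Na gate rates (1/ms): (a_m, b_m, a_h, b_h, a_p, b_p)."""
    a_m = q10_1 * 6.57 * _vtrap(v + 20.4, 10.3)
    b_m = q10_1 * 0.304 * _vtrap(-(v + 25.7), 9.16)
    a_h = q10_1 * 0.34 * _vtrap(-(v + 114.0), 11.0)
    b_h = q10_1 * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    a_p = q10_2 * 0.0353 * _vtrap(v + 27.0, 10.2)
    b_p = q10_2 * 0.000883 * _vtrap(-(v + 34.0), 10.0)
    return a_m, b_m, a_h, b_h, a_p, b_p


@njit(cache=True, inline="always")
def _rates_s(v, q10_3):
    """Slow-K gate rates (1/ms): (a_s, b_s)."""
    a_s = q10_3 * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    b_s = q10_3 * 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return a_s, b_s


@njit(cache=True)
def steady_gates(v, q10_1, q10_2, q10_3):
    a_m, b_m, a_h, b_h, a_p, b_p = _rates_na(v, q10_1, q10_2)
    a_s, b_s = _rates_s(v, q10_3)
    return (
        a_m / (a_m + b_m),
        a_h / (a_h + b_h),
        a_p / (a_p + b_p),
        a_s / (a_s + b_s),
    )


@njit(cache=True, inline="always")
def _solve_banded2(ab, rhs, n):
    """In-place solve of a bandwidth-2 banded system.

    ``ab[2 + r - c, c]`` holds A[r, c]; both ab and rhs are destroyed.
    """
    for j in range(n):
        piv = ab[2, j]
        for i in range(1, 3):
            r = j + i
            if r >= n:
                break
            f = ab[2 + i, j] / piv
            if f != 0.0:
                hi = j + 3 if j + 3 < n else n
                for c in range(j + 1, hi):
                    ab[2 + r - c, c] -= f * ab[2 + j - c, c]
                rhs[r] -= f * rhs[j]
    for j in range(n - 1, -1, -1):
        acc = rhs[j]
        hi = j + 3 if j + 3 < n else n
        for c in range(j + 1, hi):
            acc -= ab[2 + j - c, c] * rhs[c]
        rhs[j] = acc / ab[2, j]


@njit(cache=True)
def _build_static_band(ab_s, dt, ncomp, C, Cmy, Gmy, gpas, ga, gp, theta, th_my):
    """Band entries independent of the gating state for one step size.

    Conductances are weighted by the implicitness factor theta (the myelin
    term by th_my, which is 1 for the capacitance-free node short); for
    excitable compartments the gate-dependent conductance is added on top
    each step.
    """
    ab_s[:, :] = 0.0
    for i in range(ncomp):
        r0 = 2 * i
        r1 = 2 * i + 1
        gmem_s = C[i] / dt + theta * gpas[i]
        ab_s[2, r0] += gmem_s
        ab_s[1, r1] += -gmem_s
        ab_s[3, r0] += -gmem_s
        ab_s[2, r1] += gmem_s + Cmy[i] / dt + th_my[i] * Gmy[i]
    for i in range(ncomp - 1):
        g = theta * ga[i]
        ab_s[2, 2 * i] += g
        ab_s[2, 2 * i + 2] += g
        ab_s[0, 2 * i + 2] -= g
        ab_s[4, 2 * i] -= g
        g = theta * gp[i]
        ab_s[2, 2 * i + 1] += g
        ab_s[2, 2 * i + 3] += g
        ab_s[0, 2 * i + 3] -= g
        ab_s[4, 2 * i + 1] -= g


@njit(cache=True)
def run_cable(
    dts,          # (n_steps,) ms
    wave,         # (n_steps + 1,) stimulus scale at step endpoints
    ve_mV,        # (ncomp,) extracellular potential per unit stimulus, mV
    iinj,         # (n_steps + 1,) intracellular injection, uA
    inj_idx,      # int compartment index for iinj
    ctype,        # (ncomp,) uint8: 0 node, 1 MYSA, 2 FLUT, 3 STIN
    C,            # (ncomp,) axolemma capacitance, uF
    Cmy,          # (ncomp,) myelin capacitance, uF
    Gmy,          # (ncomp,) myelin conductance, mS
    gpas,         # (ncomp,) leak conductance, mS
    Epas,         # (ncomp,) leak reversal, mV
    gnaf,         # (ncomp,) max fast-Na conductance, mS (0 off nodes)
    gnap,         # (ncomp,) max persistent-Na conductance, mS
    gks,          # (ncomp,) max slow-K conductance, mS
    e_na,
    e_k,
    ga,           # (ncomp - 1,) intracellular axial conductance, mS
    gp,           # (ncomp - 1,) periaxonal axial conductance, mS
    v_rest,
    q10_1,
    q10_2,
    q10_3,
    record_idx,   # (nrec,) compartment indices whose Vm is recorded
    theta=0.5,    # implicitness: 0.5 Crank-Nicolson, 1.0 backward Euler
):
    ncomp = C.shape[0]
    n_steps = dts.shape[0]
    nrec = record_idx.shape[0]
    n = 2 * ncomp
    om = 1.0 - theta

    m0, h0, p0, s0 = steady_gates(v_rest, q10_1, q10_2, q10_3)
    m = np.full(ncomp, m0)
    h = np.full(ncomp, h0)
    p = np.full(ncomp, p0)
    s = np.full(ncomp, s0)

    Vi = np.empty(ncomp)
    Vp = np.empty(ncomp)
    for i in range(ncomp):
        Vp[i] = wave[0] * ve_mV[i]
        Vi[i] = v_rest + Vp[i]

    # the node sheath short has no capacitance (algebraic constraint);
    # keep its conductance fully implicit to avoid an undamped CN mode
    th_my = np.empty(ncomp)
    for i in range(ncomp):
        th_my[i] = 1.0 if Cmy[i] == 0.0 else theta

    rec = np.empty((n_steps + 1, nrec))
    for j in range(nrec):
        rec[0, j] = Vi[record_idx[j]] - Vp[record_idx[j]]

    # explicit axial residuals carried between steps (zero at rest)
    axial_old = np.zeros(ncomp)   # net intracellular axial inflow, uA
    paxial_old = np.zeros(ncomp)  # net periaxonal axial inflow, uA
    for i in range(ncomp):
        if i > 0:
            axial_old[i] += ga[i - 1] * (Vi[i - 1] - Vi[i])
            paxial_old[i] += gp[i - 1] * (Vp[i - 1] - Vp[i])
        if i < ncomp - 1:
            axial_old[i] += ga[i] * (Vi[i + 1] - Vi[i])
            paxial_old[i] += gp[i] * (Vp[i + 1] - Vp[i])

    gtot_arr = np.empty(ncomp)
    gE_arr = np.empty(ncomp)
    ab_s = np.empty((5, n))
    ab = np.empty((5, n))
    rhs = np.empty(n)
    last_dt = -1.0

    for k in range(n_steps):
        dt = dts[k]
        if dt != last_dt:
            _build_static_band(
                ab_s, dt, ncomp, C, Cmy, Gmy, gpas, ga, gp, theta, th_my
            )
            last_dt = dt
        ab[:, :] = ab_s
        w_old = wave[k]
        w_new = wave[k + 1]
        # staggered gates: advance from one step midpoint to the next
        # (a half interval on the first step) with rates frozen at V(t_k)
        if k == 0:
            dt_g = 0.5 * dt
        else:
            dt_g = 0.5 * (dts[k - 1] + dt)

        for i in range(ncomp):
            vm = Vi[i] - Vp[i]
            gdyn = 0.0
            gE = gpas[i] * Epas[i]
            tc = ctype[i]
            if tc == 0:  # node: fast Na, persistent Na, slow K
                a_m, b_m, a_h, b_h, a_p, b_p = _rates_na(vm, q10_1, q10_2)
                t = a_m + b_m
                m[i] = a_m / t + (m[i] - a_m / t) * np.exp(-dt_g * t)
                t = a_h + b_h
                h[i] = a_h / t + (h[i] - a_h / t) * np.exp(-dt_g * t)
                t = a_p + b_p
                p[i] = a_p / t + (p[i] - a_p / t) * np.exp(-dt_g * t)
                a_s, b_s = _rates_s(vm, q10_3)
                t = a_s + b_s
                s[i] = a_s / t + (s[i] - a_s / t) * np.exp(-dt_g * t)
                gna = gnaf[i] * m[i] * m[i] * m[i] * h[i] + gnap[i] * p[i] ** 3
                gk = gks[i] * s[i]
                gdyn = gna + gk
                gE += gna * e_na + gk * e_k
            elif tc <= 2:  # paranode: slow K only
                a_s, b_s = _rates_s(vm, q10_3)
                t = a_s + b_s
                s[i] = a_s / t + (s[i] - a_s / t) * np.exp(-dt_g * t)
                gk = gks[i] * s[i]
                gdyn = gk
                gE += gk * e_k

            gtot = gpas[i] + gdyn
            gtot_arr[i] = gtot
            gE_arr[i] = gE

            r0 = 2 * i
            r1 = 2 * i + 1
            if gdyn != 0.0:
                gd = theta * gdyn
                ab[2, r0] += gd
                ab[1, r1] -= gd
                ab[3, r0] -= gd
                ab[2, r1] += gd

            # half-step conductances drive the voltage midpoint:
            # I_ion ~ gtot * (theta V_new + (1-theta) V_old) - gE
            iion_expl = gtot * vm - gE
            ve_new = w_new * ve_mV[i]
            ve_old = w_old * ve_mV[i]
            cdt = C[i] / dt
            cmydt = Cmy[i] / dt
            rhs[r0] = (
                cdt * vm
                + theta * gE
                + om * (-iion_expl + axial_old[i])
            )
            rhs[r1] = (
                cmydt * (Vp[i] + ve_new - ve_old)
                + th_my[i] * Gmy[i] * ve_new
                - (1.0 - th_my[i]) * Gmy[i] * (Vp[i] - ve_old)
                - cdt * vm
                - theta * gE
                + om * (iion_expl + paxial_old[i])
            )
        # theta-weighted intracellular injection enters the axolemma row only
        if iinj[k + 1] != 0.0:
            rhs[2 * inj_idx] += theta * iinj[k + 1]
        if iinj[k] != 0.0:
            rhs[2 * inj_idx] += om * iinj[k]

        _solve_banded2(ab, rhs, n)
        bad = False
        for i in range(ncomp):
            Vi[i] = rhs[2 * i]
            Vp[i] = rhs[2 * i + 1]
            if not np.isfinite(Vi[i]):
                bad = True
        if bad:
            return rec[: k + 1]
        for i in range(ncomp):
            a = 0.0
            pa = 0.0
            if i > 0:
                a += ga[i - 1] * (Vi[i - 1] - Vi[i])
                pa += gp[i - 1] * (Vp[i - 1] - Vp[i])
            if i < ncomp - 1:
                a += ga[i] * (Vi[i + 1] - Vi[i])
                pa += gp[i] * (Vp[i + 1] - Vp[i])
            axial_old[i] = a
            paxial_old[i] = pa
        for j in range(nrec):
            rec[k + 1, j] = Vi[record_idx[j]] - Vp[record_idx[j]]

    return rec
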