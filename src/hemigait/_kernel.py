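"""Compiled closed-loop integrator (RK4, fixed step).

The population ODEs and the limb/feedback state machine are advanced
together: within one RK4 step the feedback conductances are held frozen
(they change on the slow limb time scale), then the stance-progress
coordinates and limb phases are updated from the freshly integrated flexor
outputs.  All arrays are float64; the kernel is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel"]

#: status codes returned by the kernel
OK = 0
NONFINITE = 1


@njit(cache=True)
def _derivs(
    V, h, fb, WE, WI, driveE, fbE, fbI,
    is_burster, C, gNaP, gL, ENa, EL, EsE, EsI,
    Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
    Vout_min, Vout_inv_range,
    dV, dh,
):
    n = V.shape[0]
    out = np.empty(n)
    for j in range(n):
        x = (V[j] - Vout_min[j]) * Vout_inv_range[j]
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        out[j] = x
    for i in range(n):
        gEi = driveE[i]
        gIi = 0.0
        for j in range(n):
            gEi += WE[i, j] * out[j]
            gIi += WI[i, j] * out[j]
        for k in range(4):
            gEi += fbE[i, k] * fb[k]
            gIi += fbI[i, k] * fb[k]
        Vi = V[i]
        I = -gL[i] * (Vi - EL[i]) - gEi * (Vi - EsE) - gIi * (Vi - EsI)
        if is_burster[i]:
            m = 1.0 / (1.0 + np.exp((Vi - Vm_half[i]) / km[i]))
            I -= gNaP[i] * m * h[i] * (Vi - ENa[i])
            hinf = 1.0 / (1.0 + np.exp((Vi - Vh_half[i]) / kh[i]))
            tau = tau0[i] / np.cosh((Vi - Vtau[i]) / ktau[i])
            dh[i] = (hinf - h[i]) / tau
        else:
            dh[i] = 0.0
        dV[i] = I / C[i]


@njit(cache=True)
def simulate_kernel(
    WE, WI, driveE, fbE, fbI,
    psiL, psiR, betaL, betaR, kE1, kE2,
    is_burster, C, gNaP, gL, ENa, EL, EsE, EsI,
    Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
    Vout_min, Vout_max,
    iFL, iFR, iEL, iER,
    theta_lo, theta_hi,
    dt, n_steps, rec_every,
    V, h, swingL, swingR, sL, sR,
):
    """Integrate the closed-loop system for ``n_steps`` of ``dt`` ms.

    Returns (status, bad_index, bad_time, out_rec, s_rec, phase_rec, V, h)
    where out_rec is (n_rec, n) decimated normalised outputs, s_rec is
    (n_rec, 2) stance progress and phase_rec is (n_rec, 2) with 1 = swing.
    """
    n = V.shape[0]
    inv_range = 1.0 / (Vout_max - Vout_min)
    n_rec = n_steps // rec_every + 1
    out_rec = np.empty((n_rec, n))
    s_rec = np.empty((n_rec, 2))
    phase_rec = np.empty((n_rec, 2), dtype=np.int8)

    k1V = np.empty(n); k1h = np.empty(n)
    k2V = np.empty(n); k2h = np.empty(n)
    k3V = np.empty(n); k3h = np.empty(n)
    k4V = np.empty(n); k4h = np.empty(n)
    Vt = np.empty(n); ht = np.empty(n)
    fb = np.empty(4)

    def _out(idx):
        x = (V[idx] - Vout_min[idx]) * inv_range[idx]
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        return x

    rec = 0
    status = OK
    bad_index = -1
    bad_time = -1.0
    for step in range(n_steps + 1):
        # record
        if step % rec_every == 0:
            for j in range(n):
                x = (V[j] - Vout_min[j]) * inv_range[j]
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                out_rec[rec, j] = x
            s_rec[rec, 0] = sL
            s_rec[rec, 1] = sR
            phase_rec[rec, 0] = 1 if swingL else 0
            phase_rec[rec, 1] = 1 if swingR else 0
            rec += 1
        if step == n_steps:
            break

        # feedback values for this step (frozen during the RK4 substeps);
        # presynaptic scaling by the source side's drive
        fb[0] = 0.0 if swingL else psiL * kE1 * sL
        fb[1] = 0.0 if swingR else psiR * kE1 * sR
        fb[2] = 0.0 if swingL else psiL * kE2 * _out(iEL)
        fb[3] = 0.0 if swingR else psiR * kE2 * _out(iER)

        _derivs(V, h, fb, WE, WI, driveE, fbE, fbI, is_burster, C, gNaP, gL,
                ENa, EL, EsE, EsI, Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
                Vout_min, inv_range, k1V, k1h)
        for j in range(n):
            Vt[j] = V[j] + 0.5 * dt * k1V[j]
            ht[j] = h[j] + 0.5 * dt * k1h[j]
        _derivs(Vt, ht, fb, WE, WI, driveE, fbE, fbI, is_burster, C, gNaP, gL,
                ENa, EL, EsE, EsI, Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
                Vout_min, inv_range, k2V, k2h)
        for j in range(n):
            Vt[j] = V[j] + 0.5 * dt * k2V[j]
            ht[j] = h[j] + 0.5 * dt * k2h[j]
        _derivs(Vt, ht, fb, WE, WI, driveE, fbE, fbI, is_burster, C, gNaP, gL,
                ENa, EL, EsE, EsI, Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
                Vout_min, inv_range, k3V, k3h)
        for j in range(n):
            Vt[j] = V[j] + dt * k3V[j]
            ht[j] = h[j] + dt * k3h[j]
        _derivs(Vt, ht, fb, WE, WI, driveE, fbE, fbI, is_burster, C, gNaP, gL,
                ENa, EL, EsE, EsI, Vm_half, km, Vh_half, kh, tau0, Vtau, ktau,
                Vout_min, inv_range, k4V, k4h)
        for j in range(n):
            V[j] += dt / 6.0 * (k1V[j] + 2.0 * k2V[j] + 2.0 * k3V[j] + k4V[j])
            h[j] += dt / 6.0 * (k1h[j] + 2.0 * k2h[j] + 2.0 * k3h[j] + k4h[j])
            if h[j] < 0.0:
                h[j] = 0.0
            elif h[j] > 1.0:
                h[j] = 1.0

        # limb state machines
        outFL = _out(iFL)
        outFR = _out(iFR)
        if swingL:
            if outFL < theta_lo:
                swingL = False
                sL = 0.0
        else:
            sL += betaL * dt * 1e-3
            if outFL > theta_hi:
                swingL = True
        if swingR:
            if outFR < theta_lo:
                swingR = False
                sR = 0.0
        else:
            sR += betaR * dt * 1e-3
            if outFR > theta_hi:
                swingR = True

        if step % 1000 == 0:
            for j in range(n):
                if not np.isfinite(V[j]):
                    status = NONFINITE
                    bad_index = j
                    bad_time = step * dt
                    break
            if status != OK:
                break

    if status != OK:
        out_rec = out_rec[:rec]
        s_rec = s_rec[:rec]
        phase_rec = phase_rec[:rec]
    return status, bad_index, bad_time, out_rec, s_rec, phase_rec, V, h
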