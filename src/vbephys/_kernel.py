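"""Fixed-step RK4 integration kernel for the single-compartment neuron model.

Compiled with numba when available; a no-op decorator keeps the pure-Python
path semantically identical (just slower).  All quantities in the patch-clamp
unit system: mV, ms, pA, nS, pF (note pA = nS * mV and mV/ms = pA/pF).

State vector layout: [V, mT, hT, r, q, mNa, hNa, nK]
Gate kinetics matrix ``kin``: one row per gate (mT, hT, r, q), columns
[v_half, slope, tau_form, p0..p5].  tau forms:
  0: constant              tau = p0
  1: bell                  tau = p0 + p1*exp(-((V-p2)/p3)^2)
  2: reciprocal double-exp tau = p0 + p1/(exp(-(V-p2)/p3) + exp((V-p4)/p5))
  3: piecewise (T-type h)  tau = exp((V-p0)/p1) if V < p4 else p2 + exp(-(V-p3)/p5)

Parameter vector ``pvec``:
[Cm, g_leak, E_leak, gT, E_Ca, gh, E_h, gHVA, gNa, E_Na, gK, E_K, VT, phi_n]
(gT/gh already scaled by their block fractions; phi_n scales the
delayed-rectifier rates, setting tonic firing rates).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco

N_STATE = 8


@njit(cache=True)
def _xinf(v_half, slope, v):
    return 1.0 / (1.0 + math.exp((v_half - v) / slope))


@njit(cache=True)
def _tau(form, p, v):
    if form == 0:
        return p[0]
    elif form == 1:
        z = (v - p[2]) / p[3]
        return p[0] + p[1] * math.exp(-z * z)
    elif form == 2:
        return p[0] + p[1] / (math.exp(-(v - p[2]) / p[3]) + math.exp((v - p[4]) / p[5]))
    else:
        if v < p[4]:
            return math.exp((v - p[0]) / p[1])
        return p[2] + math.exp(-(v - p[3]) / p[5])


@njit(cache=True)
def _vtrap(x, y):
    # x / (exp(x/y) - 1) with the singularity removed
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def _deriv(y, drive, mode, pvec, kin, rs_eff, dy):
    """dy/dt.  In current clamp ``drive`` is injected pA; in voltage clamp it
    is the command potential (mV) applied through ``rs_eff`` (MOhm)."""
    v = y[0]
    cm = pvec[0]
    # gated currents (pA)
    i_leak = pvec[1] * (v - pvec[2])
    i_t = pvec[3] * y[1] * y[1] * y[2] * (v - pvec[4])
    i_h = pvec[5] * y[3] * (v - pvec[6])
    i_hva = pvec[7] * y[4] * y[4] * (v - pvec[4])
    i_na = pvec[8] * y[5] * y[5] * y[5] * y[6] * (v - pvec[9])
    i_k = pvec[10] * y[7] * y[7] * y[7] * y[7] * (v - pvec[11])
    i_ion = i_leak + i_t + i_h + i_hva + i_na + i_k
    if mode == 0:  # current clamp
        dy[0] = (drive - i_ion) / cm
    else:  # voltage clamp through residual series resistance
        i_clamp = (drive - v) / rs_eff * 1000.0  # mV/MOhm -> nA -> pA
        dy[0] = (i_clamp - i_ion) / cm
    # voltage-gated relaxation gates
    for g in range(4):
        vh = kin[g, 0]
        sl = kin[g, 1]
        form = int(kin[g, 2])
        tau = _tau(form, kin[g, 3:9], v)
        xinf = _xinf(vh, sl, v)
        dy[1 + g] = (xinf - y[1 + g]) / tau
    # HH sodium / delayed-rectifier rates (1/ms), threshold-shifted by VT
    vt = pvec[12]
    u = v - vt
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * math.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
    phi_n = pvec[13]
    an = phi_n * 0.032 * _vtrap(15.0 - u, 5.0)
    bn = phi_n * 0.5 * math.exp(-(u - 10.0) / 40.0)
    dy[5] = am * (1.0 - y[5]) - bm * y[5]
    dy[6] = ah * (1.0 - y[6]) - bh * y[6]
    dy[7] = an * (1.0 - y[7]) - bn * y[7]
    return i_ion


@njit(cache=True)
def steady_gates(v, kin, y):
    """Fill gate entries of state ``y`` with their steady-state values at v."""
    for g in range(4):
        y[1 + g] = _xinf(kin[g, 0], kin[g, 1], v)
    # HH gates at rest
    # reuse rate expressions via a derivative call is awkward; inline:
    return y


@njit(cache=True)
def _hh_inf(v, vt):
    u = v - vt
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * math.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + math.exp(-(u - 40.0) / 5.0))
    an = 0.032 * _vtrap(15.0 - u, 5.0)
    bn = 0.5 * math.exp(-(u - 10.0) / 40.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@njit(cache=True)
def init_state(v, pvec, kin):
    y = np.empty(N_STATE)
    y[0] = v
    steady_gates(v, kin, y)
    m, h, n = _hh_inf(v, pvec[12])
    y[5] = m
    y[6] = h
    y[7] = n
    return y


@njit(cache=True)
def integrate(command, dt, substeps, y, mode, pvec, kin, rs_eff, record):
    """RK4 over one sweep; command is piecewise constant per sample.

    ``record``: output array of len(command); membrane potential in current
    clamp, clamp current (pA) in voltage clamp.  Returns the index of the
    first non-finite sample, or -1 on success.  ``y`` is updated in place.
    """
    n = command.shape[0]
    h = dt / substeps
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)
    for i in range(n):
        drive = command[i]
        if mode == 0:
            record[i] = y[0]
        else:
            record[i] = (drive - y[0]) / rs_eff * 1000.0
        if not math.isfinite(record[i]):
            return i
        for _ in range(substeps):
            _deriv(y, drive, mode, pvec, kin, rs_eff, k1)
            for j in range(N_STATE):
                yt[j] = y[j] + 0.5 * h * k1[j]
            _deriv(yt, drive, mode, pvec, kin, rs_eff, k2)
            for j in range(N_STATE):
                yt[j] = y[j] + 0.5 * h * k2[j]
            _deriv(yt, drive, mode, pvec, kin, rs_eff, k3)
            for j in range(N_STATE):
                yt[j] = y[j] + h * k3[j]
            _deriv(yt, drive, mode, pvec, kin, rs_eff, k4)
            for j in range(N_STATE):
                y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return -1
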