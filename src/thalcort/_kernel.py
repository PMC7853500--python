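"""JIT-compiled fixed-step RK4 loop for the delayed conductance dynamics.

Semantics mirror :func:`thalcort.model.state_derivative` exactly; the two are
cross-checked in the test suite.  Delay terms are read from the step-resolution
voltage history with linear interpolation and frozen across the four stages of
each step.
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)


@njit(cache=True, fastmath=False)
def _ncdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True, fastmath=False)
def _deriv(V, g, fire_tc, fire_ct, G4, mh, kappa, vrev, alpha, C, gL, VL, VR,
           Sigma, cls, u, dV, dg):
    n = V.shape[0]
    # instantaneous firing
    fire0 = np.empty(n)
    for j in range(n):
        fire0[j] = _ncdf((V[j] - VR) / Sigma[j])
    for i in range(n):
        cur = gL * (VL - V[i]) + u[i]
        # synaptic channels
        for k in range(4):
            vs = 0.0
            for j in range(n):
                w = G4[k, i, j]
                if w != 0.0:
                    c = cls[i, j]
                    if c == 0:
                        vs += w * fire0[j]
                    elif c == 1:
                        vs += w * fire_tc[j]
                    else:
                        vs += w * fire_ct[j]
            drive = vrev[k] - V[i]
            if k == 1:  # NMDA magnesium block
                drive *= 1.0 / (1.0 + 0.2 * math.exp(-alpha * V[i]))
            cur += g[k, i] * drive
            dg[k, i] = kappa[k] * (vs - g[k, i])
        # intrinsic M- and H-currents
        for k in range(4, 6):
            cur += g[k, i] * (vrev[k] - V[i])
            dg[k, i] = kappa[k] * (mh[k - 4, i] - g[k, i])
        dV[i] = cur / C[i]


@njit(cache=True, fastmath=False)
def _delayed_fire(Vhist, k, dsteps, VR, Sigma, out):
    """Firing of each population at history time k - dsteps (linear interp)."""
    n = Vhist.shape[1]
    pos = k - dsteps
    if pos <= 0.0:
        lo = 0
        hi = 0
        w = 0.0
    else:
        lo = int(math.floor(pos))
        hi = lo + 1 if lo + 1 <= k else lo
        w = pos - lo
    for j in range(n):
        v = (1.0 - w) * Vhist[lo, j] + w * Vhist[hi, j]
        out[j] = _ncdf((v - VR) / Sigma[j])


@njit(cache=True, fastmath=False)
def rk4_delay_loop(V0, g0, G4, mh, kappa, vrev, alpha, C, gL, VL, VR, Sigma,
                   cls, d_tc, d_ct, u_half, dt, n_steps):
    n = V0.shape[0]
    V_out = np.empty((n_steps + 1, n))
    g_out = np.empty((n_steps + 1, 6, n))
    V_out[0] = V0
    g_out[0] = g0

    fire_tc = np.empty(n)
    fire_ct = np.empty(n)
    dV = np.empty((4, n))
    dg = np.empty((4, 6, n))
    Vtmp = np.empty(n)
    gtmp = np.empty((6, n))
    s_tc = d_tc / dt
    s_ct = d_ct / dt

    for k in range(n_steps):
        _delayed_fire(V_out, k, s_tc, VR, Sigma, fire_tc)
        _delayed_fire(V_out, k, s_ct, VR, Sigma, fire_ct)
        V = V_out[k]
        g = g_out[k]
        u0 = u_half[2 * k]
        uh = u_half[2 * k + 1]
        u1 = u_half[2 * k + 2]

        _deriv(V, g, fire_tc, fire_ct, G4, mh, kappa, vrev, alpha, C, gL, VL,
               VR, Sigma, cls, u0, dV[0], dg[0])
        for i in range(n):
            Vtmp[i] = V[i] + 0.5 * dt * dV[0, i]
            for c in range(6):
                gtmp[c, i] = g[c, i] + 0.5 * dt * dg[0, c, i]
        _deriv(Vtmp, gtmp, fire_tc, fire_ct, G4, mh, kappa, vrev, alpha, C, gL,
               VL, VR, Sigma, cls, uh, dV[1], dg[1])
        for i in range(n):
            Vtmp[i] = V[i] + 0.5 * dt * dV[1, i]
            for c in range(6):
                gtmp[c, i] = g[c, i] + 0.5 * dt * dg[1, c, i]
        _deriv(Vtmp, gtmp, fire_tc, fire_ct, G4, mh, kappa, vrev, alpha, C, gL,
               VL, VR, Sigma, cls, uh, dV[2], dg[2])
        for i in range(n):
            Vtmp[i] = V[i] + dt * dV[2, i]
            for c in range(6):
                gtmp[c, i] = g[c, i] + dt * dg[2, c, i]
        _deriv(Vtmp, gtmp, fire_tc, fire_ct, G4, mh, kappa, vrev, alpha, C, gL,
               VL, VR, Sigma, cls, u1, dV[3], dg[3])

        ok = True
        for i in range(n):
            v = V[i] + dt / 6.0 * (dV[0, i] + 2.0 * dV[1, i] + 2.0 * dV[2, i] + dV[3, i])
            if not math.isfinite(v):
                ok = False
            V_out[k + 1, i] = v
            for c in range(6):
                gv = g[c, i] + dt / 6.0 * (dg[0, c, i] + 2.0 * dg[1, c, i]
                                           + 2.0 * dg[2, c, i] + dg[3, c, i])
                if not math.isfinite(gv):
                    ok = False
                g_out[k + 1, c, i] = gv
        if not ok:
            return V_out, g_out, k + 1
    return V_out, g_out, -1
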