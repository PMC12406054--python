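"""Numba-compiled fixed-step integrator for the neuronal + hemodynamic cascade.

The generative model couples a bilinear neuronal state equation

    dz/dt = (A(u)) z + C u,   A(u)[r,c] = A[r,c] + sum_j u_j B_j[r,c]   (r != c)
                              A(u)[r,r] = -0.5 * exp(A[r,r] + sum_j u_j B_j[r,r])

with, per region, the balloon–windkessel observation cascade (vasodilatory
signal s, inflow f, venous volume v, deoxyhemoglobin q):

    ds/dt = z - kappa s - gamma (f - 1)
    df/dt = s
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f E(f)/E0 - v**(1/alpha) q / v,   E(f) = 1 - (1 - E0)**(1/f)

BOLD (percent signal change):

    y = 100 V0 eps (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))

Integration is explicit 4th-order Runge–Kutta at a fixed microtime step with
the inputs held piecewise-constant over each step.  States reset to baseline
(z = s = 0, f = v = q = 1) at run boundaries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# canonical balloon-model constants (per-region free parameters scale
# kappa, tau and eps multiplicatively via exp(log-parameters))
KAPPA0 = 0.64   # 1/s, vasodilatory signal decay
GAMMA0 = 0.32   # 1/s, flow autoregulation
TAU0 = 2.0      # s, venous transit time
ALPHA0 = 0.32   # Grubb's vessel stiffness exponent
E0 = 0.4        # resting oxygen extraction fraction
V0 = 0.04       # resting venous blood volume fraction
K1 = 7.0 * E0
K2 = 2.0
K3 = 2.0 * E0 - 0.2
LOG_1_E0 = np.log(1.0 - E0)

N_HEMO_STATES = 4  # s, f, v, q

# exogenous (driving) inputs enter the neuronal equation as C u / INPUT_SCALE,
# the convention under which published C values of O(0.1-1) keep neuronal
# excursions small and the balloon cascade inside its physical regime
INPUT_SCALE = 16.0


@njit(cache=True)
def _deriv(z, s, lf, lv, lq, A, Bsum, expd, Cu, kappa, tau,
           dz, ds, dlf, dlv, dlq):
    # flow, volume and deoxyhemoglobin are integrated in log space so they
    # stay positive even under sustained negative (mean-centered) drive
    n = z.shape[0]
    for r in range(n):
        acc = Cu[r]
        for c in range(n):
            if r == c:
                acc += -0.5 * expd[r] * z[c]
            else:
                acc += (A[r, c] + Bsum[r, c]) * z[c]
        dz[r] = acc
        # clamp to the physical window; the caller's post-step check
        # rejects trajectories that actually leave it
        clf = min(max(lf[r], -20.0), 20.0)
        clv = min(max(lv[r], -20.0), 20.0)
        clq = min(max(lq[r], -20.0), 20.0)
        f = np.exp(clf)
        v = np.exp(clv)
        q = np.exp(clq)
        ds[r] = z[r] - kappa[r] * s[r] - GAMMA0 * (f - 1.0)
        dlf[r] = s[r] / f
        fv = np.exp(clv / ALPHA0)            # v ** (1/alpha)
        ef = 1.0 - np.exp(LOG_1_E0 / f)      # 1 - (1 - E0) ** (1/f)
        dlv[r] = (f - fv) / (tau[r] * v)
        dlq[r] = (f * ef / E0 - fv * q / v) / (tau[r] * q)


@njit(cache=True)
def integrate_bold(A, B, C, diagA, diagB, kappa, tau, eps,
                   U, dt, reset_steps, sample_steps, out):
    """Integrate the full cascade and write sampled BOLD into ``out``.

    A : (n, n) endogenous coupling, diagonal ignored (see diagA)
    B : (m, n, n) modulatory coupling, diagonals ignored (see diagB)
    C : (n, k) driving input weights
    diagA : (n,) raw log-scale self-connection parameters
    diagB : (m, n) raw modulatory self-connection parameters
    kappa, tau, eps : (n,) per-region hemodynamic constants (already scaled)
    U : (n_steps, k) microtime inputs, piecewise constant per step
    reset_steps : sorted step indices at which states reset to baseline
    sample_steps : step indices at which BOLD is sampled (rows of ``out``)
    out : (T, n) output buffer, percent signal change

    Returns the 1-based step index at which the hemodynamic states left the
    physical domain (volume/deoxyhemoglobin non-positive or non-finite), or 0
    on success.
    """
    n = A.shape[0]
    m = B.shape[0]
    n_steps = U.shape[0]

    z = np.zeros(n)
    s = np.zeros(n)
    lf = np.zeros(n)
    lv = np.zeros(n)
    lq = np.zeros(n)

    Bsum = np.zeros((n, n))
    expd = np.zeros(n)

    # RK4 work buffers
    kz = np.zeros((4, n)); ks = np.zeros((4, n)); kf = np.zeros((4, n))
    kv = np.zeros((4, n)); kq = np.zeros((4, n))
    zt = np.zeros(n); st = np.zeros(n); ft = np.zeros(n)
    vt = np.zeros(n); qt = np.zeros(n)
    Cu = np.zeros(n)

    i_reset = 0
    i_samp = 0
    half = 0.5 * dt

    for step in range(n_steps):
        if i_reset < reset_steps.shape[0] and reset_steps[i_reset] == step:
            for r in range(n):
                z[r] = 0.0; s[r] = 0.0; lf[r] = 0.0; lv[r] = 0.0; lq[r] = 0.0
            i_reset += 1

        while i_samp < sample_steps.shape[0] and sample_steps[i_samp] == step:
            for r in range(n):
                v = np.exp(lv[r]); q = np.exp(lq[r])
                out[i_samp, r] = 100.0 * V0 * eps[r] * (
                    K1 * (1.0 - q) + K2 * (1.0 - q / v) + K3 * (1.0 - v))
            i_samp += 1

        # inputs for this step (driving term uses the 1/16 convention)
        for r in range(n):
            acc = 0.0
            for k in range(U.shape[1]):
                acc += C[r, k] * U[step, k]
            Cu[r] = acc / INPUT_SCALE
        for r in range(n):
            dr = diagA[r]
            for j in range(m):
                dr += U[step, 1 + j] * diagB[j, r] if U.shape[1] > 1 + j else 0.0
            expd[r] = np.exp(dr)
            for c in range(n):
                bs = 0.0
                for j in range(m):
                    if U.shape[1] > 1 + j:
                        bs += U[step, 1 + j] * B[j, r, c]
                Bsum[r, c] = bs

        _deriv(z, s, lf, lv, lq, A, Bsum, expd, Cu, kappa, tau,
               kz[0], ks[0], kf[0], kv[0], kq[0])
        for r in range(n):
            zt[r] = z[r] + half * kz[0, r]; st[r] = s[r] + half * ks[0, r]
            ft[r] = lf[r] + half * kf[0, r]; vt[r] = lv[r] + half * kv[0, r]
            qt[r] = lq[r] + half * kq[0, r]
        _deriv(zt, st, ft, vt, qt, A, Bsum, expd, Cu, kappa, tau,
               kz[1], ks[1], kf[1], kv[1], kq[1])
        for r in range(n):
            zt[r] = z[r] + half * kz[1, r]; st[r] = s[r] + half * ks[1, r]
            ft[r] = lf[r] + half * kf[1, r]; vt[r] = lv[r] + half * kv[1, r]
            qt[r] = lq[r] + half * kq[1, r]
        _deriv(zt, st, ft, vt, qt, A, Bsum, expd, Cu, kappa, tau,
               kz[2], ks[2], kf[2], kv[2], kq[2])
        for r in range(n):
            zt[r] = z[r] + dt * kz[2, r]; st[r] = s[r] + dt * ks[2, r]
            ft[r] = lf[r] + dt * kf[2, r]; vt[r] = lv[r] + dt * kv[2, r]
            qt[r] = lq[r] + dt * kq[2, r]
        _deriv(zt, st, ft, vt, qt, A, Bsum, expd, Cu, kappa, tau,
               kz[3], ks[3], kf[3], kv[3], kq[3])

        sixth = dt / 6.0
        ok = True
        for r in range(n):
            z[r] += sixth * (kz[0, r] + 2 * kz[1, r] + 2 * kz[2, r] + kz[3, r])
            s[r] += sixth * (ks[0, r] + 2 * ks[1, r] + 2 * ks[2, r] + ks[3, r])
            lf[r] += sixth * (kf[0, r] + 2 * kf[1, r] + 2 * kf[2, r] + kf[3, r])
            lv[r] += sixth * (kv[0, r] + 2 * kv[1, r] + 2 * kv[2, r] + kv[3, r])
            lq[r] += sixth * (kq[0, r] + 2 * kq[1, r] + 2 * kq[2, r] + kq[3, r])
            if (not np.isfinite(z[r]) or not np.isfinite(lq[r])
                    or abs(z[r]) > 1e6 or abs(lf[r]) > 20.0
                    or abs(lv[r]) > 20.0 or abs(lq[r]) > 20.0):
                ok = False
        if not ok:
            return step + 1

    # samples that coincide with the final state
    while i_samp < sample_steps.shape[0]:
        for r in range(n):
            v = np.exp(lv[r]); q = np.exp(lq[r])
            out[i_samp, r] = 100.0 * V0 * eps[r] * (
                K1 * (1.0 - q) + K2 * (1.0 - q / v) + K3 * (1.0 - v))
        i_samp += 1
    return 0


@njit(cache=True)
def integrate_neuronal(A, B, C, diagA, diagB, U, dt, reset_steps, out):
    """RK4 on the neuronal states only; writes the full trajectory to ``out``
    ((n_steps, n), state *before* each step's update). Returns 0, or the
    failing 1-based step on divergence."""
    n = A.shape[0]
    m = B.shape[0]
    n_steps = U.shape[0]
    z = np.zeros(n)
    Bsum = np.zeros((n, n))
    diag_raw = np.zeros(n)
    Cu = np.zeros(n)
    k1 = np.zeros(n); k2 = np.zeros(n); k3 = np.zeros(n); k4 = np.zeros(n)
    zt = np.zeros(n)
    i_reset = 0
    for step in range(n_steps):
        if i_reset < reset_steps.shape[0] and reset_steps[i_reset] == step:
            for r in range(n):
                z[r] = 0.0
            i_reset += 1
        for r in range(n):
            out[step, r] = z[r]
        for r in range(n):
            acc = 0.0
            for k in range(U.shape[1]):
                acc += C[r, k] * U[step, k]
            Cu[r] = acc / INPUT_SCALE
            dr = diagA[r]
            for j in range(m):
                if U.shape[1] > 1 + j:
                    dr += U[step, 1 + j] * diagB[j, r]
            diag_raw[r] = dr
            for c in range(n):
                bs = 0.0
                for j in range(m):
                    if U.shape[1] > 1 + j:
                        bs += U[step, 1 + j] * B[j, r, c]
                Bsum[r, c] = bs

        for r in range(n):
            acc = Cu[r]
            for c in range(n):
                acc += (-0.5 * np.exp(diag_raw[r]) * z[c] if r == c
                        else (A[r, c] + Bsum[r, c]) * z[c])
            k1[r] = acc
        for r in range(n):
            zt[r] = z[r] + 0.5 * dt * k1[r]
        for r in range(n):
            acc = Cu[r]
            for c in range(n):
                acc += (-0.5 * np.exp(diag_raw[r]) * zt[c] if r == c
                        else (A[r, c] + Bsum[r, c]) * zt[c])
            k2[r] = acc
        for r in range(n):
            zt[r] = z[r] + 0.5 * dt * k2[r]
        for r in range(n):
            acc = Cu[r]
            for c in range(n):
                acc += (-0.5 * np.exp(diag_raw[r]) * zt[c] if r == c
                        else (A[r, c] + Bsum[r, c]) * zt[c])
            k3[r] = acc
        for r in range(n):
            zt[r] = z[r] + dt * k3[r]
        for r in range(n):
            acc = Cu[r]
            for c in range(n):
                acc += (-0.5 * np.exp(diag_raw[r]) * zt[c] if r == c
                        else (A[r, c] + Bsum[r, c]) * zt[c])
            k4[r] = acc
        ok = True
        for r in range(n):
            z[r] += dt / 6.0 * (k1[r] + 2 * k2[r] + 2 * k3[r] + k4[r])
            if not np.isfinite(z[r]):
                ok = False
        if not ok:
            return step + 1
    return 0
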