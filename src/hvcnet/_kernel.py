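"""Compiled network integrator.

The production integrator is a fixed-step RK4 scheme for the deterministic
vector field with an Euler–Maruyama noise current frozen over each step
(``I_noise = sigma * xi / sqrt(dt)``, ``xi ~ N(0,1)`` per neuron per step).
The equations integrated here are the same as in :mod:`hvcnet.cells` and
:mod:`hvcnet.synapses`; agreement between the two implementations and with
an adaptive reference integrator is asserted in the test suite.

State vector layout (length ``n_state``):

- ``Y[0:N]``            membrane potentials
- ``Y[off[i]:off[i]+k]`` per-neuron gate/Ca block
  (RA: h,n,s,e,Ca; X: h,n,mT,hT,rf,rs,Ca; INT: h,n,mT,hT,r,Ca)
- ``Y[syn0:]``          synaptic gates, one per edge

Kinetic constants are packed per class in a ``(3, NK)`` matrix ``K``
(see ``K_*`` index constants below); per-neuron maximal conductances in
``Gn`` with columns ``G_*``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# columns of the per-neuron conductance matrix Gn
G_L, G_NA, G_K, G_CAL, G_CAT, G_SK, G_A, G_H = range(8)
NG = 8

# kinetic-constant layout (per class row of K)
(
    K_M_HALF, K_M_K,
    K_H_HALF, K_H_K, K_H_TMIN, K_H_TAMP, K_H_THALF, K_H_TK,
    K_N_HALF, K_N_K, K_N_TMIN, K_N_TAMP, K_N_THALF, K_N_TK,
    K_S_HALF, K_S_K,
    K_MT_HALF, K_MT_K, K_MT_TSCALE,
    K_HT_HALF, K_HT_K, K_HT_TMIN2, K_HT_TAMP2, K_HT_THALF2, K_HT_TK2,
    K_R_HALF, K_R_K, K_R_TSCALE, K_R_FFRAC, K_R_SLOWF,
    K_A_HALF, K_A_K, K_A_TAU,
    K_E_HALF, K_E_K, K_E_TAU,
    K_SK_KD,
    K_CA_INFLUX, K_CA_TAU, K_CA_REST,
    K_E_NA, K_E_K_REV, K_E_CA, K_E_H,
    K_S_TAU,
) = range(45)
NK = 45

CLS_RA, CLS_X, CLS_INT = 0, 1, 2
GATES_PER_CLASS = (5, 7, 6)  # gate/Ca block lengths (state dim minus V)


@njit(cache=True, fastmath=False)
def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=False)
def _tau_cat_m(V, scale):
    return scale * (
        0.612 + 1.0 / (np.exp(-(V + 131.6) / 16.7) + np.exp((V + 16.8) / 18.2))
    )




@njit(cache=True, fastmath=False)
def _tau_h(V, scale):
    return scale / (np.exp(-14.59 - 0.086 * V) + np.exp(-1.87 + 0.0701 * V))


@njit(cache=True, fastmath=False)
def rhs(
    Y, dY, cls, C, Gn, EL, K, off,
    pre, post, gsyn, esyn, asyn, bsyn, syn0,
    rel_thr, rel_slope, Iext, Isyn_buf,
):
    N = cls.shape[0]
    nsyn = pre.shape[0]

    # synaptic currents and gate kinetics
    for i in range(N):
        Isyn_buf[i] = 0.0
    for e in range(nsyn):
        s = Y[syn0 + e]
        Vpre = Y[pre[e]]
        T = 1.0 / (1.0 + np.exp(-(Vpre - rel_thr) / rel_slope))
        dY[syn0 + e] = asyn[e] * T * (1.0 - s) - bsyn[e] * s
        Isyn_buf[post[e]] += gsyn[e] * s * (Y[post[e]] - esyn[e])

    for i in range(N):
        V = Y[i]
        c = cls[i]
        b = off[i]
        ENa = K[c, K_E_NA]
        EK = K[c, K_E_K_REV]
        ECa = K[c, K_E_CA]

        h = Y[b]
        n = Y[b + 1]

        m = _sig((V - K[c, K_M_HALF]) / K[c, K_M_K])
        INa = Gn[i, G_NA] * m * m * m * h * (V - ENa)
        IK = Gn[i, G_K] * n * n * n * n * (V - EK)
        IL = Gn[i, G_L] * (V - EL[i])

        hinf = _sig((V - K[c, K_H_HALF]) / K[c, K_H_K])
        htau = K[c, K_H_TMIN] + K[c, K_H_TAMP] * _sig(
            (V - K[c, K_H_THALF]) / K[c, K_H_TK])
        ninf = _sig((V - K[c, K_N_HALF]) / K[c, K_N_K])
        ntau = K[c, K_N_TMIN] + K[c, K_N_TAMP] * _sig(
            (V - K[c, K_N_THALF]) / K[c, K_N_TK])
        dY[b] = (hinf - h) / htau
        dY[b + 1] = (ninf - n) / ntau

        ICaT = 0.0
        Iother = 0.0
        if c == CLS_RA:
            # gate block: h, n, s(CaL, slow), e(A inactivation), Ca;
            # A-current activation is instantaneous.
            sCaL = Y[b + 2]
            ee = Y[b + 3]
            Ca = Y[b + 4]
            ICaL = Gn[i, G_CAL] * sCaL * sCaL * (V - ECa)
            ainf = _sig((V - K[c, K_A_HALF]) / K[c, K_A_K])
            IA = Gn[i, G_A] * ainf * ee * (V - EK)
            ISK = Gn[i, G_SK] * (Ca * Ca / (Ca * Ca + K[c, K_SK_KD] ** 2)) * (V - EK)
            Iother = IA + ISK
            sinf = _sig((V - K[c, K_S_HALF]) / K[c, K_S_K])
            einf = _sig((V - K[c, K_E_HALF]) / K[c, K_E_K])
            dY[b + 2] = (sinf - sCaL) / K[c, K_S_TAU]
            dY[b + 3] = (einf - ee) / K[c, K_E_TAU]
            ica = ICaL
            dY[b + 4] = -K[c, K_CA_INFLUX] * ica - (Ca - K[c, K_CA_REST]) / K[c, K_CA_TAU]
        else:
            sCaL = _sig((V - K[c, K_S_HALF]) / K[c, K_S_K])
            ICaL = Gn[i, G_CAL] * sCaL * sCaL * (V - ECa)
            mT = Y[b + 2]
            hT = Y[b + 3]
            mtinf = _sig((V - K[c, K_MT_HALF]) / K[c, K_MT_K])
            htinf = _sig((V - K[c, K_HT_HALF]) / K[c, K_HT_K])
            dY[b + 2] = (mtinf - mT) / _tau_cat_m(V, K[c, K_MT_TSCALE])
            httau = K[c, K_HT_TMIN2] + K[c, K_HT_TAMP2] * _sig(
                (V - K[c, K_HT_THALF2]) / K[c, K_HT_TK2])
            dY[b + 3] = (htinf - hT) / httau
            ICaT = Gn[i, G_CAT] * mT * mT * hT * (V - ECa)
            rinf = _sig((V - K[c, K_R_HALF]) / K[c, K_R_K])
            rtau = _tau_h(V, K[c, K_R_TSCALE])
            if c == CLS_X:
                rf = Y[b + 4]
                rs = Y[b + 5]
                Ca = Y[b + 6]
                dY[b + 4] = (rinf - rf) / rtau
                dY[b + 5] = (rinf - rs) / (K[c, K_R_SLOWF] * rtau)
                ropen = K[c, K_R_FFRAC] * rf + (1.0 - K[c, K_R_FFRAC]) * rs
                IH = Gn[i, G_H] * ropen * (V - K[c, K_E_H])
                ISK = Gn[i, G_SK] * (Ca * Ca / (Ca * Ca + K[c, K_SK_KD] ** 2)) * (V - EK)
                Iother = IH + ISK
                cab = b + 6
            else:
                r = Y[b + 4]
                Ca = Y[b + 5]
                dY[b + 4] = (rinf - r) / rtau
                IH = Gn[i, G_H] * r * (V - K[c, K_E_H])
                Iother = IH
                cab = b + 5
            ica = ICaL + ICaT
            dY[cab] = -K[c, K_CA_INFLUX] * ica - (Ca - K[c, K_CA_REST]) / K[c, K_CA_TAU]

        Iion = IL + INa + IK + ICaL + ICaT + Iother
        dY[i] = (-Iion + Iext[i] - Isyn_buf[i]) / C[i]


@njit(cache=True, fastmath=False)
def integrate(
    Y0, cls, C, Gn, EL, K, off,
    pre, post, gsyn, esyn, asyn, bsyn, syn0,
    rel_thr, rel_slope,
    p_target, p_amp, p_on, p_off,
    dt, n_steps, record_stride,
    sigma, noise_seed,
    det_thr, refractory, max_spikes,
):
    """Fixed-step RK4 with per-step frozen external current.

    Returns (Vrec, spike_times, spike_counts, blew_up_step, blew_up_neuron,
    final_state).
    Spike times are upward crossings of ``det_thr`` (linear interpolation
    between steps) separated by at least ``refractory`` ms.
    """
    N = cls.shape[0]
    nst = Y0.shape[0]
    Y = Y0.copy()
    k1 = np.empty(nst)
    k2 = np.empty(nst)
    k3 = np.empty(nst)
    k4 = np.empty(nst)
    Ytmp = np.empty(nst)
    Iext = np.zeros(N)
    Isyn_buf = np.empty(N)

    n_rec = n_steps // record_stride + 1
    Vrec = np.empty((N, n_rec))
    for i in range(N):
        Vrec[i, 0] = Y[i]

    spike_times = np.empty((N, max_spikes))
    spike_counts = np.zeros(N, dtype=np.int64)
    last_spike = np.full(N, -1e9)
    Vprev = np.empty(N)

    np.random.seed(noise_seed)
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    npulse = p_target.shape[0]

    for step in range(n_steps):
        t = step * dt
        for i in range(N):
            Iext[i] = 0.0
        for p in range(npulse):
            if p_on[p] <= t < p_off[p]:
                Iext[p_target[p]] += p_amp[p]
        if sigma > 0.0:
            for i in range(N):
                Iext[i] += sigma * np.random.normal() * inv_sqrt_dt

        for i in range(N):
            Vprev[i] = Y[i]

        rhs(Y, k1, cls, C, Gn, EL, K, off, pre, post, gsyn, esyn, asyn, bsyn,
            syn0, rel_thr, rel_slope, Iext, Isyn_buf)
        for j in range(nst):
            Ytmp[j] = Y[j] + 0.5 * dt * k1[j]
        rhs(Ytmp, k2, cls, C, Gn, EL, K, off, pre, post, gsyn, esyn, asyn, bsyn,
            syn0, rel_thr, rel_slope, Iext, Isyn_buf)
        for j in range(nst):
            Ytmp[j] = Y[j] + 0.5 * dt * k2[j]
        rhs(Ytmp, k3, cls, C, Gn, EL, K, off, pre, post, gsyn, esyn, asyn, bsyn,
            syn0, rel_thr, rel_slope, Iext, Isyn_buf)
        for j in range(nst):
            Ytmp[j] = Y[j] + dt * k3[j]
        rhs(Ytmp, k4, cls, C, Gn, EL, K, off, pre, post, gsyn, esyn, asyn, bsyn,
            syn0, rel_thr, rel_slope, Iext, Isyn_buf)
        for j in range(nst):
            Y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        t_next = t + dt
        for i in range(N):
            if not np.isfinite(Y[i]):
                return Vrec, spike_times, spike_counts, step, i, Y
            if Vprev[i] <= det_thr < Y[i]:
                frac = (det_thr - Vprev[i]) / (Y[i] - Vprev[i])
                ts = t + frac * dt
                if ts - last_spike[i] >= refractory:
                    cnt = spike_counts[i]
                    if cnt < max_spikes:
                        spike_times[i, cnt] = ts
                        spike_counts[i] = cnt + 1
                    last_spike[i] = ts

        if (step + 1) % record_stride == 0:
            r = (step + 1) // record_stride
            for i in range(N):
                Vrec[i, r] = Y[i]

    return Vrec, spike_times, spike_counts, -1, -1, Y
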