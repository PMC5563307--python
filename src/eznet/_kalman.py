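"""Kalman recursion kernel for tv-MVAR coefficient tracking.

The filter factorizes into independent scalar-observation filters per target
channel (all channels share the lagged regressor vector).  Trials aligned on
the discharge peak are processed sequentially at each time step, so an
ensemble of segments sharpens the estimate at every latency.

A numba-compiled kernel is used when numba is importable; a pure-numpy
implementation with identical semantics is the fallback (and the reference
in tests).
"""

from __future__ import annotations

import numpy as np


def _kalman_numpy(trials, p, uc, leak, var0):
    K, M, N = trials.shape
    d = M * p
    A_state = np.zeros((M, d))
    P = np.tile(np.eye(d), (M, 1, 1))
    v = var0.copy()
    V = np.diag(var0).astype(float)
    coeffs = np.full((N, M, d), np.nan)
    resid_cov = np.full((N, M, M), np.nan)
    innov = np.full((N, K, M), np.nan)
    for t in range(p, N):
        for k in range(K):
            # z[(l-1)M + j] = x_j(t-l)
            z = trials[k][:, t - p : t][:, ::-1].T.ravel()
            e = trials[k][:, t] - A_state @ z
            P_pred = (1.0 + uc) * P
            Pz = P_pred @ z  # (M, d)
            S = Pz @ z + v
            Kg = Pz / S[:, None]
            A_state = (1.0 - leak) * (A_state + Kg * e[:, None])
            P = P_pred - Kg[:, :, None] * Pz[:, None, :]
            P = 0.5 * (P + P.transpose(0, 2, 1))
            v = (1.0 - uc) * v + uc * e * e
            V = (1.0 - uc) * V + uc * np.outer(e, e)
            innov[t, k] = e
        if not np.all(np.isfinite(A_state)):
            return coeffs, resid_cov, innov, t
        coeffs[t] = A_state
        resid_cov[t] = V
    return coeffs, resid_cov, innov, -1


def _kalman_loops(trials, p, uc, leak, var0):  # pragma: no cover - numba twin
    K, M, N = trials.shape
    d = M * p
    A_state = np.zeros((M, d))
    P = np.zeros((M, d, d))
    for i in range(M):
        for a in range(d):
            P[i, a, a] = 1.0
    v = var0.copy()
    V = np.zeros((M, M))
    for i in range(M):
        V[i, i] = var0[i]
    coeffs = np.full((N, M, d), np.nan)
    resid_cov = np.full((N, M, M), np.nan)
    innov = np.full((N, K, M), np.nan)
    z = np.empty(d)
    for t in range(p, N):
        for k in range(K):
            for l in range(p):
                for j in range(M):
                    z[l * M + j] = trials[k, j, t - 1 - l]
            for i in range(M):
                pred = 0.0
                for a in range(d):
                    pred += A_state[i, a] * z[a]
                e_i = trials[k, i, t] - pred
                innov[t, k, i] = e_i
            e = innov[t, k]
            for i in range(M):
                Pi = (1.0 + uc) * P[i]
                Pz = Pi @ z
                S = z @ Pz + v[i]
                e_i = e[i]
                for a in range(d):
                    Kg = Pz[a] / S
                    A_state[i, a] = (1.0 - leak) * (A_state[i, a] + Kg * e_i)
                for a in range(d):
                    Ka = Pz[a] / S
                    for b in range(d):
                        Pi[a, b] = Pi[a, b] - Ka * Pz[b]
                for a in range(d):
                    for b in range(a + 1, d):
                        m = 0.5 * (Pi[a, b] + Pi[b, a])
                        Pi[a, b] = m
                        Pi[b, a] = m
                P[i] = Pi
                v[i] = (1.0 - uc) * v[i] + uc * e_i * e_i
            for i in range(M):
                for j in range(M):
                    V[i, j] = (1.0 - uc) * V[i, j] + uc * e[i] * e[j]
        finite = True
        for i in range(M):
            for a in range(d):
                if not np.isfinite(A_state[i, a]):
                    finite = False
        if not finite:
            return coeffs, resid_cov, innov, t
        coeffs[t] = A_state
        resid_cov[t] = V
    return coeffs, resid_cov, innov, -1


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _kalman_jit = njit(cache=True, fastmath=False)(_kalman_loops)
except Exception:  # pragma: no cover
    _kalman_jit = None


def kalman_filter(trials, p, uc, leak, var0, use_numba=True):
    """Run the recursion; returns (coeffs (N,M,Mp), resid_cov, innov, t_diverged)."""
    if use_numba and _kalman_jit is not None:
        return _kalman_jit(trials, p, uc, leak, var0)
    return _kalman_numpy(trials, p, uc, leak, var0)
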