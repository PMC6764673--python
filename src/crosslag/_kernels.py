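"""Compiled inner loops for the ML discrepancy and its gradient.

The discrepancy of a 2T-variate covariance structure is evaluated thousands
of times per Monte Carlo study, on matrices no larger than 16 x 16, where
array-library call overhead dominates.  These numba kernels carry out the
block recursion, its forward sensitivities, the Cholesky-based discrepancy
and the gradient contraction with explicit scalar loops.  A pure-numpy
implementation of the same computation lives in ``estimation._Discrepancy``
(``value_and_grad_numpy``) and the two are cross-validated in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PENALTY = 1e6


@njit(cache=True)
def _recursion_sens(theta: np.ndarray, T: int):
    """V_t and dV_t/dtheta_j (j < 10) of the deviation-state recursion."""
    B = np.empty((2, 2))
    B[0, 0], B[0, 1], B[1, 0], B[1, 1] = theta[0], theta[2], theta[3], theta[1]
    DB = np.zeros((4, 2, 2))
    DB[0, 0, 0] = DB[1, 1, 1] = DB[2, 0, 1] = DB[3, 1, 0] = 1.0
    V = np.empty((T, 2, 2))
    V[0, 0, 0], V[0, 1, 1] = theta[7], theta[8]
    V[0, 0, 1] = V[0, 1, 0] = theta[9]
    dV = np.zeros((T, 10, 2, 2))
    dV[0, 7, 0, 0] = dV[0, 8, 1, 1] = 1.0
    dV[0, 9, 0, 1] = dV[0, 9, 1, 0] = 1.0
    for t in range(1, T):
        Vp = V[t - 1]
        W = np.empty((2, 2))   # B V
        P = np.empty((2, 2))   # V B'
        for a in range(2):
            for b in range(2):
                W[a, b] = B[a, 0] * Vp[0, b] + B[a, 1] * Vp[1, b]
                P[a, b] = Vp[a, 0] * B[b, 0] + Vp[a, 1] * B[b, 1]
        for a in range(2):
            for b in range(2):
                V[t, a, b] = W[a, 0] * B[b, 0] + W[a, 1] * B[b, 1]
        V[t, 0, 0] += theta[4]
        V[t, 1, 1] += theta[5]
        V[t, 0, 1] += theta[6]
        V[t, 1, 0] += theta[6]
        for j in range(10):
            dVp = dV[t - 1, j]
            X = np.empty((2, 2))
            for a in range(2):
                for b in range(2):
                    X[a, b] = B[a, 0] * dVp[0, b] + B[a, 1] * dVp[1, b]
            for a in range(2):
                for b in range(2):
                    dV[t, j, a, b] = X[a, 0] * B[b, 0] + X[a, 1] * B[b, 1]
            if j < 4:
                D = DB[j]
                for a in range(2):
                    for b in range(2):
                        acc = 0.0
                        for k in range(2):
                            acc += D[a, k] * P[k, b] + W[a, k] * D[b, k]
                        dV[t, j, a, b] += acc
        dV[t, 4, 0, 0] += 1.0
        dV[t, 5, 1, 1] += 1.0
        dV[t, 6, 0, 1] += 1.0
        dV[t, 6, 1, 0] += 1.0
    return B, DB, V, dV


@njit(cache=True)
def _assemble_sigma(theta: np.ndarray, B: np.ndarray, V: np.ndarray, T: int,
                    has_trait: bool, has_error: bool) -> np.ndarray:
    p = 2 * T
    sigma = np.zeros((p, p))
    C = V.copy()
    for t in range(T):
        for a in range(2):
            for b in range(2):
                sigma[2 * t + a, 2 * t + b] = V[t, a, b]
    for s in range(1, T):
        m = T - s
        Cn = np.empty((m, 2, 2))
        for u in range(m):
            for a in range(2):
                for b in range(2):
                    Cn[u, a, b] = B[a, 0] * C[u, 0, b] + B[a, 1] * C[u, 1, b]
            t = u + s
            for a in range(2):
                for b in range(2):
                    sigma[2 * t + a, 2 * u + b] = Cn[u, a, b]
                    sigma[2 * u + b, 2 * t + a] = Cn[u, a, b]
        C = Cn
    if has_trait:
        tvx, tvy, tvc = theta[10], theta[11], theta[12]
        for t in range(T):
            for u in range(T):
                sigma[2 * t, 2 * u] += tvx
                sigma[2 * t + 1, 2 * u + 1] += tvy
                sigma[2 * t, 2 * u + 1] += tvc
                sigma[2 * t + 1, 2 * u] += tvc
    if has_error:
        px, py, pxy = theta[13], theta[14], theta[15]
        for t in range(T):
            sigma[2 * t, 2 * t] += px
            sigma[2 * t + 1, 2 * t + 1] += py
            sigma[2 * t, 2 * t + 1] += pxy
            sigma[2 * t + 1, 2 * t] += pxy
    return sigma


@njit(cache=True)
def _cholesky(sigma: np.ndarray):
    """Lower Cholesky factor; flag False when not positive definite."""
    p = sigma.shape[0]
    L = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = sigma[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _inv_from_cholesky(L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    Linv = np.zeros((p, p))
    for i in range(p):
        Linv[i, i] = 1.0 / L[i, i]
        for j in range(i):
            s = 0.0
            for k in range(j, i):
                s -= L[i, k] * Linv[k, j]
            Linv[i, j] = s / L[i, i]
    out = np.empty((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = 0.0
            for k in range(i, p):
                s += Linv[k, i] * Linv[k, j]
            out[i, j] = s
            out[j, i] = s
    return out


@njit(cache=True)
def _contract(A: np.ndarray, B: np.ndarray, DB: np.ndarray, V: np.ndarray,
              dV: np.ndarray, T: int, n_par: int) -> np.ndarray:
    """g_j = sum_{t,u} <A(t,u), dSigma(t,u)/dtheta_j> for symmetric A."""
    g = np.zeros(n_par)
    for t in range(T):
        for j in range(10):
            acc = 0.0
            for a in range(2):
                for b in range(2):
                    acc += A[2 * t + a, 2 * t + b] * dV[t, j, a, b]
            g[j] += acc
    C = V.copy()
    dC = dV.copy()
    for s in range(1, T):
        m = T - s
        Cn = np.empty((m, 2, 2))
        dCn = np.empty((m, 10, 2, 2))
        for u in range(m):
            for a in range(2):
                for b in range(2):
                    Cn[u, a, b] = B[a, 0] * C[u, 0, b] + B[a, 1] * C[u, 1, b]
            for j in range(10):
                for a in range(2):
                    for b in range(2):
                        val = B[a, 0] * dC[u, j, 0, b] + B[a, 1] * dC[u, j, 1, b]
                        if j < 4:
                            val += DB[j, a, 0] * C[u, 0, b] + DB[j, a, 1] * C[u, 1, b]
                        dCn[u, j, a, b] = val
            t = u + s
            for j in range(10):
                acc = 0.0
                for a in range(2):
                    for b in range(2):
                        acc += A[2 * t + a, 2 * u + b] * dCn[u, j, a, b]
                g[j] += 2.0 * acc
        C = Cn
        dC = dCn
    if n_par > 10:
        s00 = s01 = s11 = 0.0
        for t in range(T):
            for u in range(T):
                s00 += A[2 * t, 2 * u]
                s11 += A[2 * t + 1, 2 * u + 1]
                s01 += A[2 * t, 2 * u + 1]
        g[10], g[11], g[12] = s00, s11, 2.0 * s01
    if n_par > 13:
        d00 = d01 = d11 = 0.0
        for t in range(T):
            d00 += A[2 * t, 2 * t]
            d11 += A[2 * t + 1, 2 * t + 1]
            d01 += A[2 * t, 2 * t + 1]
        g[13], g[14], g[15] = d00, d11, 2.0 * d01
    return g


@njit(cache=True)
def fml_value_and_grad(theta16: np.ndarray, T: int, has_trait: bool,
                       has_error: bool, n_par: int, S: np.ndarray,
                       logdet_S: float):
    """F_ML (means profiled out) and its exact gradient, or the PD penalty."""
    p = 2 * T
    for j in range(16):
        if not np.isfinite(theta16[j]):
            return 1e12, np.zeros(n_par)
    B, DB, V, dV = _recursion_sens(theta16, T)
    sigma = _assemble_sigma(theta16, B, V, T, has_trait, has_error)
    for i in range(p):
        for j in range(p):
            if not np.isfinite(sigma[i, j]):
                return 1e12, np.zeros(n_par)
    L, ok = _cholesky(sigma)
    if not ok:
        w, Q = np.linalg.eigh(sigma)
        lam = w[0]
        if lam >= 0.0:
            return PENALTY, np.zeros(n_par)
        v = Q[:, 0]
        Wmat = np.outer(v, v)
        g = -PENALTY * _contract(Wmat, B, DB, V, dV, T, n_par)
        return PENALTY * (1.0 - lam), g
    sinv = _inv_from_cholesky(L)
    logdet = 0.0
    for i in range(p):
        logdet += np.log(L[i, i])
    logdet *= 2.0
    tr = 0.0
    for i in range(p):
        for j in range(p):
            tr += sinv[i, j] * S[i, j]
    val = logdet - logdet_S + tr - p
    if not np.isfinite(val):
        return 1e12, np.zeros(n_par)
    A = sinv - sinv @ S @ sinv
    g = _contract(A, B, DB, V, dV, T, n_par)
    return val, g
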