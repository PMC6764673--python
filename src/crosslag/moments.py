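"""Model-implied means and covariances of the stacked observation vector.

The deviation process (x*_t, y*_t) follows the first-order bivariate
recursion state_t = B state_{t-1} + d_t with coefficient matrix

    B = [[beta_x, gamma_x],
        [gamma_y, beta_y]]

and innovation covariance Omega.  Its within-time covariance satisfies
V_1 = initial block, V_t = B V_{t-1} B' + Omega, and its cross-time
covariance Cov(state_t, state_{t-s}) = B^s V_{t-s}.  Trait factors add a
constant 2x2 block to every time-pair block (RI-CLPM, STARTS); occasion
measurement error adds a 2x2 block to same-time blocks only (STARTS).
"""

from __future__ import annotations

import numpy as np

from .params import CrossLagParams, MomentStructure, ModelKind

__all__ = ["implied_moments", "implied_cov_from_values", "state_covariances"]


def state_covariances(B: np.ndarray, omega: np.ndarray, init: np.ndarray,
                      T: int) -> np.ndarray:
    """Within-time covariances V_1..V_T of the deviation process, shape (T,2,2)."""
    V = np.empty((T, 2, 2))
    V[0] = init
    for t in range(1, T):
        V[t] = B @ V[t - 1] @ B.T + omega
    return V


def implied_cov_from_values(theta: np.ndarray, T: int, kind: ModelKind) -> np.ndarray:
    """Build the 2T x 2T implied covariance from the 16-slot scalar vector.

    ``theta`` is the non-mean parameter block in pack order, padded with
    zeros for blocks the kind excludes.  This is the hot path of ML fitting;
    it makes no legality checks and never symmetrizes away negative
    variances, so improper parameter values propagate faithfully.
    """
    bx, by, gx, gy, ox, oy, oxy, ivx, ivy, ivc = theta[:10]
    B = np.array([[bx, gx], [gy, by]])
    omega = np.array([[ox, oxy], [oxy, oy]])
    V = state_covariances(B, omega, np.array([[ivx, ivc], [ivc, ivy]]), T)

    M = np.zeros((T, T, 2, 2))
    rng = np.arange(T)
    M[rng, rng] = V
    # lag-s blocks: Cov(state_t, state_{t-s}) = B^s V_{t-s}, filled iteratively
    C = V
    for s in range(1, T):
        C = np.matmul(B, C[: T - s])
        M[rng[s:], rng[: T - s]] = C

    lower = M.transpose(0, 2, 1, 3).reshape(2 * T, 2 * T)
    D = np.zeros((T, T, 2, 2))
    D[rng, rng] = V
    diag = D.transpose(0, 2, 1, 3).reshape(2 * T, 2 * T)
    sigma = lower + lower.T - diag

    if kind.has_trait:
        tvx, tvy, tvc = theta[10], theta[11], theta[12]
        sigma += np.tile(np.array([[tvx, tvc], [tvc, tvy]]), (T, T))
    if kind.has_error:
        px, py, pxy = theta[13], theta[14], theta[15]
        psi = np.array([[px, pxy], [pxy, py]])
        for t in range(T):
            sigma[2 * t:2 * t + 2, 2 * t:2 * t + 2] += psi
    return sigma


def implied_moments(params: CrossLagParams, T: int,
                    kind: ModelKind | str) -> MomentStructure:
    """Model-implied mean vector and covariance matrix under ``kind``.

    Parameters
    ----------
    params
        Full parameter set; fields structurally excluded by ``kind`` must be
        zero.
    T
        Number of measurement occasions (>= 2).
    kind
        Which of the three models the parameters describe.
    """
    kind = ModelKind.coerce(kind)
    if T < 2:
        raise ValueError("implied moments require T >= 2")
    if params.T != T:
        raise ValueError(f"params carry {params.T} means per variable, expected {T}")
    vals = params.scalar_values()
    if not np.all(np.isfinite(vals)) or not np.all(np.isfinite(params.mu_x)) \
            or not np.all(np.isfinite(params.mu_y)):
        raise ValueError("non-finite parameter values")
    if not params.structurally_consistent(kind):
        raise ValueError(f"params carry nonzero blocks excluded under {kind.name}")

    mean = np.column_stack([params.mu_x, params.mu_y]).ravel()
    cov = implied_cov_from_values(vals, T, kind)
    cov = 0.5 * (cov + cov.T)  # exact symmetry for downstream factorizations
    return MomentStructure(mean=mean, cov=cov, T=T)
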