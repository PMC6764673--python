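"""Maximum-likelihood fitting of the cross-lagged models to sample moments.

The fit minimizes the normal-theory discrepancy

    F_ML(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^{-1}) - 2T
                  + (xbar - mu(theta))' Sigma(theta)^{-1} (xbar - mu(theta))

over the model parameters.  Because the mean structure is saturated (one
free mean per variable per occasion), its ML solution is exactly the sample
mean for any covariance parameters, so the optimizer profiles the means out
and searches only over the covariance-side parameters.  Variance parameters
are optimized unconstrained: negative variance estimates are a legitimate
outcome and the primary marker of an improper solution.

Standard errors come from the observed information (numerical Hessian of
-lnL at the optimum, central differences); the reciprocal condition number
of that Hessian feeds the singular-Hessian criterion for improper solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm

from ._kernels import fml_value_and_grad
from .moments import implied_cov_from_values, implied_moments
from .params import (CrossLagParams, MomentStructure, ModelKind,
                     free_parameter_count, min_timepoints, n_cov_parameters,
                     pack_parameters, unpack_parameters)

__all__ = ["FitResult", "fit_ml", "fit_models", "start_values", "fml",
           "standard_errors", "classify_improper", "wald_significance",
           "information_criteria", "fit_indices", "WaldTest"]

#: default reciprocal-condition-number threshold below which the approximate
#: Hessian is treated as singular
DEFAULT_RCOND_THRESHOLD = 1e-10

_PENALTY = 1e6  # base of the smooth penalty used when Sigma(theta) is not PD


@dataclass
class FitResult:
    """One ML fit of one model kind to one set of sample moments."""

    kind: ModelKind
    estimates: CrossLagParams
    minus2_loglik: float
    fml: float
    se: np.ndarray                 # aligned with pack order (means first)
    converged: bool
    hessian_rcond: float
    improper: bool
    improper_reason: str           # none | negative_variance | singular_hessian | nonconvergence
    k: int
    N: int
    T: int
    aic: float
    bic: float
    n_fev: int = 0
    theta: np.ndarray = field(default=None, repr=False)  # covariance-side vector

    @property
    def packed(self) -> np.ndarray:
        return pack_parameters(self.estimates, self.kind, self.T)


# sparse basis patterns of the 2x2 parameter blocks, pack order
_DB = np.zeros((4, 2, 2))
_DB[0, 0, 0] = _DB[1, 1, 1] = _DB[2, 0, 1] = _DB[3, 1, 0] = 1.0
_DSYM = np.zeros((3, 2, 2))
_DSYM[0, 0, 0] = _DSYM[1, 1, 1] = 1.0
_DSYM[2, 0, 1] = _DSYM[2, 1, 0] = 1.0


class _Discrepancy:
    """F_ML as a function of the covariance-side parameter vector."""

    def __init__(self, S: np.ndarray, T: int, kind: ModelKind):
        self.T = T
        self.kind = kind
        self.S = S
        sign, self.logdet_S = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(self.logdet_S):
            raise ValueError("sample covariance matrix must be positive definite")
        self.p = 2 * T
        self.n_fev = 0

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        full = np.zeros(16)
        full[: theta.shape[0]] = theta
        return implied_cov_from_values(full, self.T, self.kind)

    def __call__(self, theta: np.ndarray) -> float:
        self.n_fev += 1
        sigma = self.sigma(theta)
        if not np.all(np.isfinite(sigma)):
            return 1e12
        try:
            c = cho_factor(sigma, lower=True, check_finite=False)
        except LinAlgError:
            # smooth push back toward the positive-definite region
            w = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
            return _PENALTY * (1.0 - min(float(w[0]), 0.0))
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        tr = np.trace(cho_solve(c, self.S, check_finite=False))
        val = logdet - self.logdet_S + tr - self.p
        return float(val) if np.isfinite(val) else 1e12

    # -- exact gradient via forward sensitivities ---------------------------
    def _recursion_with_sens(self, theta: np.ndarray):
        """Within-time covariances V_t and their sensitivities to theta[:10]."""
        T = self.T
        bx, by, gx, gy, ox, oy, oxy, ivx, ivy, ivc = theta[:10]
        B = np.array([[bx, gx], [gy, by]])
        omega = np.array([[ox, oxy], [oxy, oy]])
        V = np.empty((T, 2, 2))
        V[0] = [[ivx, ivc], [ivc, ivy]]
        dV = np.zeros((T, 10, 2, 2))
        dV[0, 7:10] = _DSYM
        dBT = np.swapaxes(_DB, 1, 2)
        for t in range(1, T):
            VB = V[t - 1] @ B.T
            V[t] = B @ VB + omega
            d = B @ dV[t - 1] @ B.T
            d[:4] += _DB @ VB + (B @ V[t - 1]) @ dBT
            d[4:7] += _DSYM
            dV[t] = d
        return B, V, dV

    def _assemble(self, theta: np.ndarray, B: np.ndarray, V: np.ndarray) -> np.ndarray:
        T = self.T
        M = np.zeros((T, T, 2, 2))
        r = np.arange(T)
        M[r, r] = V
        C = V
        for s in range(1, T):
            C = np.matmul(B, C[: T - s])
            M[r[s:], r[: T - s]] = C
        lower = M.transpose(0, 2, 1, 3).reshape(self.p, self.p)
        D = np.zeros((T, T, 2, 2))
        D[r, r] = V
        diag = D.transpose(0, 2, 1, 3).reshape(self.p, self.p)
        sigma = lower + lower.T - diag
        if self.kind.has_trait and theta.shape[0] > 10:
            tvx, tvy, tvc = theta[10:13]
            sigma += np.tile(np.array([[tvx, tvc], [tvc, tvy]]), (T, T))
        if self.kind.has_error and theta.shape[0] > 13:
            px, py, pxy = theta[13:16]
            psi = np.array([[px, pxy], [pxy, py]])
            for t in range(T):
                sigma[2 * t:2 * t + 2, 2 * t:2 * t + 2] += psi
        return sigma

    def _contract(self, Ablk: np.ndarray, B: np.ndarray, V: np.ndarray,
                  dV: np.ndarray, n_par: int) -> np.ndarray:
        """Gradient sum_{t,u} <A(t,u), dSigma(t,u)/dtheta> for symmetric A."""
        T = self.T
        r = np.arange(T)
        g = np.zeros(n_par)
        Adiag = Ablk[r, r]
        g[:10] = np.einsum("tab,tjab->j", Adiag, dV)
        C_prev, dC_prev = V, dV
        for s in range(1, T):
            C_cur = np.matmul(B, C_prev[: T - s])
            dC_cur = np.matmul(B, dC_prev[: T - s])
            dC_cur[:, :4] += np.einsum("jab,ubc->ujac", _DB, C_prev[: T - s])
            A_s = Ablk[r[s:], r[: T - s]]
            g[:10] += 2.0 * np.einsum("uab,ujab->j", A_s, dC_cur)
            C_prev, dC_prev = C_cur, dC_cur
        if n_par > 10:
            Asum = Ablk.sum(axis=(0, 1))
            g[10], g[11], g[12] = Asum[0, 0], Asum[1, 1], 2.0 * Asum[0, 1]
        if n_par > 13:
            Ad = Adiag.sum(axis=0)
            g[13], g[14], g[15] = Ad[0, 0], Ad[1, 1], 2.0 * Ad[0, 1]
        return g

    def value_and_grad(self, theta: np.ndarray):
        """F_ML and its exact gradient via the compiled kernel."""
        self.n_fev += 1
        theta = np.ascontiguousarray(theta, dtype=float)
        n_par = theta.shape[0]
        full = np.zeros(16)
        full[:n_par] = theta
        val, g = fml_value_and_grad(full, self.T, self.kind.has_trait,
                                    self.kind.has_error, n_par, self.S,
                                    self.logdet_S)
        return float(val), g

    def value_and_grad_numpy(self, theta: np.ndarray):
        """Reference implementation of :meth:`value_and_grad` in plain numpy."""
        self.n_fev += 1
        theta = np.asarray(theta, dtype=float)
        n_par = theta.shape[0]
        T, p = self.T, self.p
        if not np.all(np.isfinite(theta)):
            return 1e12, np.zeros(n_par)
        B, V, dV = self._recursion_with_sens(theta)
        sigma = self._assemble(theta, B, V)
        if not np.all(np.isfinite(sigma)):
            return 1e12, np.zeros(n_par)
        try:
            c = cho_factor(sigma, lower=True, check_finite=False)
        except LinAlgError:
            # penalty pushing back toward PD, with its exact gradient through
            # the smallest eigenvalue
            w, Q = np.linalg.eigh(0.5 * (sigma + sigma.T))
            lam, v = float(w[0]), Q[:, 0]
            vb = v.reshape(T, 2)
            Wblk = vb[:, None, :, None] * vb[None, :, None, :]
            g = -_PENALTY * self._contract(Wblk, B, V, dV, n_par)
            return _PENALTY * (1.0 - min(lam, 0.0)), (g if lam < 0 else np.zeros(n_par))
        eye = np.eye(p)
        sinv = cho_solve(c, eye, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        tr = float(np.sum(sinv * self.S))
        val = logdet - self.logdet_S + tr - p
        if not np.isfinite(val):
            return 1e12, np.zeros(n_par)
        A = sinv - sinv @ self.S @ sinv
        Ablk = A.reshape(T, 2, T, 2).transpose(0, 2, 1, 3)
        g = self._contract(Ablk, B, V, dV, n_par)
        return float(val), g


def fml(params: CrossLagParams, moments: MomentStructure,
        kind: ModelKind | str) -> float:
    """Full discrepancy F_ML at arbitrary parameters, mean term included."""
    kind = ModelKind.coerce(kind)
    implied = implied_moments(params, moments.T, kind)
    c = cho_factor(implied.cov, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    sign, logdet_S = np.linalg.slogdet(moments.cov)
    tr = np.trace(cho_solve(c, moments.cov, check_finite=False))
    d = moments.mean - implied.mean
    quad = float(d @ cho_solve(c, d, check_finite=False))
    return float(logdet - logdet_S + tr - 2 * moments.T + quad)


# ---------------------------------------------------------------------------
# starting values

def _block(S: np.ndarray, t: int, u: int) -> np.ndarray:
    return S[2 * t:2 * t + 2, 2 * u:2 * u + 2]


def start_values(moments: MomentStructure, kind: ModelKind | str) -> np.ndarray:
    """Deterministic moment-based starting vector (full pack order).

    Means start at the sample means.  The lag-0 variance is split by kind:
    the CLPM assigns it all to the deviation process; the RI-CLPM carves out
    the smallest cross-time covariance as trait variance; the STARTS model
    additionally reserves a fixed tenth of the lag-0 variance for occasion
    error.  Lagged coefficients come from pooled lag-1 least squares on the
    trait-corrected blocks.  Every division is guarded so degenerate input
    (zero variance, duplicated columns) still yields a finite vector.
    """
    kind = ModelKind.coerce(kind)
    T = moments.T
    S = moments.cov
    lag0 = np.stack([_block(S, t, t) for t in range(T)])
    scale = float(np.mean(lag0[:, [0, 1], [0, 1]]))
    if not np.isfinite(scale) or scale <= 0:
        scale = 1.0

    phi = np.zeros((2, 2))
    if kind.has_trait:
        cross_xx = [_block(S, u, t)[0, 0] for t in range(T) for u in range(t + 1, T)]
        cross_yy = [_block(S, u, t)[1, 1] for t in range(T) for u in range(t + 1, T)]
        cross_xy = [_block(S, u, t)[0, 1] for t in range(T) for u in range(t + 1, T)]
        phi_xx = float(np.clip(min(cross_xx), 0.02 * scale, 0.8 * lag0[:, 0, 0].min(initial=scale)))
        phi_yy = float(np.clip(min(cross_yy), 0.02 * scale, 0.8 * lag0[:, 1, 1].min(initial=scale)))
        cap = 0.9 * math.sqrt(phi_xx * phi_yy)
        phi_xy = float(np.clip(np.median(cross_xy), -cap, cap))
        phi = np.array([[phi_xx, phi_xy], [phi_xy, phi_yy]])

    psi = np.zeros((2, 2))
    if kind.has_error:
        psi_xx = 0.1 * float(lag0[:, 0, 0].mean())
        psi_yy = 0.1 * float(lag0[:, 1, 1].mean())
        psi_xy = 0.1 * float(lag0[:, 0, 1].mean())
        cap = 0.9 * math.sqrt(max(psi_xx, 1e-8) * max(psi_yy, 1e-8))
        psi = np.array([[max(psi_xx, 0.01 * scale), np.clip(psi_xy, -cap, cap)],
                        [0.0, max(psi_yy, 0.01 * scale)]])
        psi[1, 0] = psi[0, 1]

    def _pd_clamp(blk: np.ndarray) -> np.ndarray:
        out = blk.copy()
        out[0, 0] = max(out[0, 0], 0.05 * scale)
        out[1, 1] = max(out[1, 1], 0.05 * scale)
        cap = 0.95 * math.sqrt(out[0, 0] * out[1, 1])
        out[0, 1] = out[1, 0] = float(np.clip(out[0, 1], -cap, cap))
        return out

    dev = np.stack([_pd_clamp(lag0[t] - phi - psi) for t in range(T)])

    num = np.zeros((2, 2))
    den = np.zeros((2, 2))
    for t in range(1, T):
        num += _block(S, t, t - 1) - phi
        den += dev[t - 1]
    try:
        B = num @ np.linalg.inv(den)
    except np.linalg.LinAlgError:
        B = num @ np.linalg.pinv(den)
    B = np.clip(B, -0.95, 0.95)
    if not np.all(np.isfinite(B)):
        B = np.zeros((2, 2))

    resid = np.zeros((2, 2))
    for t in range(1, T):
        resid += dev[t] - B @ dev[t - 1] @ B.T
    resid = _pd_clamp(0.5 * (resid + resid.T) / max(T - 1, 1))

    init = _pd_clamp(dev[0])

    scal = np.array([
        B[0, 0], B[1, 1], B[0, 1], B[1, 0],
        resid[0, 0], resid[1, 1], resid[0, 1],
        init[0, 0], init[1, 1], init[0, 1],
        phi[0, 0], phi[1, 1], phi[0, 1],
        psi[0, 0], psi[1, 1], psi[0, 1],
    ])
    return np.concatenate([moments.mean, scal[: n_cov_parameters(kind)]])


# ---------------------------------------------------------------------------
# numerical derivatives

def _num_hessian(grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetrized central-difference Jacobian of an exact gradient."""
    k = x.shape[0]
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = h[j]
        H[:, j] = (grad(x + e) - grad(x - e)) / (2.0 * h[j])
    return 0.5 * (H + H.T)


def _hessian_rcond(H: np.ndarray) -> float:
    if not np.all(np.isfinite(H)):
        return 0.0
    sv = np.linalg.svd(H, compute_uv=False)
    if sv[0] <= 0:
        return 0.0
    return float(sv[-1] / sv[0])


# ---------------------------------------------------------------------------
# classification and inference helpers

def _structural_variances(est: CrossLagParams, kind: ModelKind) -> list[float]:
    out = [est.omega2_x, est.omega2_y, est.init_var_x, est.init_var_y]
    if kind.has_trait:
        out += [est.trait_var_x, est.trait_var_y]
    if kind.has_error:
        out += [est.psi2_x, est.psi2_y]
    return out


def _estimated_blocks(est: CrossLagParams, kind: ModelKind) -> list[np.ndarray]:
    blocks = [est.omega, est.init_block]
    if kind.has_trait:
        blocks.append(est.trait_block)
    if kind.has_error:
        blocks.append(est.error_block)
    return blocks


def classify_improper(fit: FitResult,
                      rcond_threshold: float = DEFAULT_RCOND_THRESHOLD,
                      count_nonconvergence: bool = False) -> tuple[bool, str]:
    """Classify a fit as an improper solution.

    Triggers, in order: (1) any structural variance estimate (residual,
    initial, trait or error variance) below zero, or an estimated block
    implying a correlation outside [-1, 1]; (2) a singular approximate
    Hessian (reciprocal condition number below ``rcond_threshold``);
    (3) optionally, nonconvergence — off by default since the improper
    definition covers only the first two.
    """
    est, kind = fit.estimates, fit.kind
    if any(v < 0 for v in _structural_variances(est, kind)):
        return True, "negative_variance"
    for blk in _estimated_blocks(est, kind):
        denom = blk[0, 0] * blk[1, 1]
        if denom > 0 and blk[0, 1] ** 2 > denom * (1.0 + 1e-10):
            return True, "negative_variance"  # out-of-range correlation
    if np.isfinite(fit.hessian_rcond) and fit.hessian_rcond < rcond_threshold:
        return True, "singular_hessian"
    if count_nonconvergence and not fit.converged:
        return True, "nonconvergence"
    return False, "none"


@dataclass
class WaldTest:
    z: float
    p: float
    significant: bool | None   # None when the SE makes the test unavailable


def wald_significance(estimate: float, se: float, alpha: float = 0.05) -> WaldTest:
    """Two-sided Wald z-test of an estimate against zero.

    ``significant`` is ``None`` (not testable) when the standard error is
    nonpositive or undefined, which is distinct from a non-significant
    result.
    """
    if not np.isfinite(se) or se <= 0:
        return WaldTest(z=float("nan"), p=float("nan"), significant=None)
    z = estimate / se
    p = 2.0 * float(norm.sf(abs(z)))
    return WaldTest(z=float(z), p=p, significant=bool(p < alpha))


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """AIC = -2lnL + 2k and BIC = -2lnL + k ln N."""
    aic = fit.minus2_loglik + 2.0 * fit.k
    bic = fit.minus2_loglik + fit.k * math.log(fit.N)
    return aic, bic


def fit_indices(fit: FitResult, moments: MomentStructure,
                N: int) -> tuple[float, float, float]:
    """RMSEA, CFI and SRMR of a converged fit.

    chi2 = (N-1) F_ML with df = distinct sample moments minus free
    parameters; RMSEA = sqrt(max(chi2-df, 0) / (df (N-1))); CFI compares
    against the independence baseline (free means and variances, zero
    covariances — its discrepancy has the closed form sum(ln S_jj) - ln|S|);
    SRMR is the root mean square of the standardized covariance residuals
    (mean residuals vanish under the saturated mean structure).
    """
    T = fit.T
    p = 2 * T
    n_moments = p + p * (p + 1) // 2
    df = n_moments - fit.k
    if df <= 0:
        return float("nan"), float("nan"), float("nan")
    chi2 = max((N - 1) * fit.fml, 0.0)
    rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (N - 1)))

    sign, logdet_S = np.linalg.slogdet(moments.cov)
    f_base = float(np.sum(np.log(np.diag(moments.cov))) - logdet_S)
    chi2_base = max((N - 1) * f_base, 0.0)
    df_base = n_moments - 2 * p
    denom = max(chi2 - df, chi2_base - df_base, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom

    implied = implied_moments(fit.estimates, T, fit.kind)
    sd = np.sqrt(np.diag(moments.cov))
    resid = (moments.cov - implied.cov) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    srmr = math.sqrt(float(np.mean(resid[iu] ** 2)))
    return rmsea, cfi, srmr


def standard_errors(fit: FitResult, moments: MomentStructure, N: int) -> np.ndarray:
    """Observed-information standard errors aligned with pack order.

    Mean-parameter SEs are sqrt(diag(Sigma_hat)/N) (the information matrix
    is block diagonal between means and covariance parameters at the
    optimum).  Covariance-parameter SEs come from the inverse numerical
    Hessian; entries that cannot be inverted to a positive variance are NaN.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    obj = _Discrepancy(moments.cov, fit.T, fit.kind)
    H = _num_hessian(lambda x: obj.value_and_grad(x)[1], fit.theta)
    return _se_from_hessian(fit, H, N)


def _se_from_hessian(fit: FitResult, H: np.ndarray, N: int) -> np.ndarray:
    k_cov = H.shape[0]
    implied = implied_moments(fit.estimates, fit.T, fit.kind)
    mean_se = np.sqrt(np.maximum(np.diag(implied.cov), 0.0) / N)
    cov_se = np.full(k_cov, np.nan)
    info = 0.5 * N * H
    if np.all(np.isfinite(info)):
        try:
            inv = np.linalg.inv(info)
            d = np.diag(inv)
            good = d > 0
            cov_se[good] = np.sqrt(d[good])
        except np.linalg.LinAlgError:
            pass
    return np.concatenate([mean_se, cov_se])


# ---------------------------------------------------------------------------
# the fit driver

def fit_ml(moments: MomentStructure, N: int, kind: ModelKind | str, *,
           compute_se: bool = True,
           rcond_threshold: float = DEFAULT_RCOND_THRESHOLD,
           count_nonconvergence: bool = False,
           maxiter: int = 2000,
           n_restarts: int = 3,
           start: np.ndarray | None = None,
           extra_starts: tuple = ()) -> FitResult:
    """Fit ``kind`` to sample moments by maximum likelihood.

    Parameters
    ----------
    moments
        Sample mean and divisor-``N`` covariance of the panel.
    N
        Number of individuals behind the moments.
    compute_se
        Skip the Hessian-based standard errors when False (the Hessian is
        still computed if needed to judge singularity).
    start, extra_starts
        Optional full pack-order starting vectors; the moment-based
        heuristic start is always tried as well.  Optimization runs from
        every candidate and keeps the lowest discrepancy, which is how
        warm-started nesting across model kinds is realized.

    Notes
    -----
    Optimizer failures are reported through ``converged=False``, never as
    exceptions; up to ``n_restarts`` deterministically jittered restarts are
    attempted first.
    """
    kind = ModelKind.coerce(kind)
    T = moments.T
    if T < min_timepoints(kind):
        raise ValueError(f"{kind.name} needs T >= {min_timepoints(kind)}, got {T}")
    k = free_parameter_count(kind, T)
    if N <= k:
        raise ValueError(f"N={N} must exceed the number of free parameters {k}")

    obj = _Discrepancy(moments.cov, T, kind)
    k_cov = n_cov_parameters(kind)
    candidates = [np.asarray(start_values(moments, kind))[2 * T:]]
    for cand in ([start] if start is not None else []) + list(extra_starts):
        cand = np.asarray(cand, dtype=float)
        candidates.append(cand[2 * T:] if cand.shape[0] == k else cand)

    # deep quasi-Newton memory pays off on the ill-conditioned STARTS surface
    opts = {"maxiter": maxiter, "maxfun": 40 * maxiter,
            "ftol": 1e-13, "gtol": 1e-6, "maxcor": 30}
    best = None
    for theta0 in candidates:
        res = minimize(obj.value_and_grad, theta0, jac=True,
                       method="L-BFGS-B", options=opts)
        if best is None or res.fun < best.fun:
            best = res
    attempt = 0
    while not best.success and attempt < n_restarts:
        rng = np.random.default_rng(90210 + attempt)
        jitter = 0.1 * (1.0 + np.abs(candidates[0])) * rng.standard_normal(k_cov)
        res = minimize(obj.value_and_grad, candidates[0] + jitter, jac=True,
                       method="L-BFGS-B", options=opts)
        if res.fun < best.fun or (res.success and not best.success
                                  and res.fun < best.fun + 1e-9):
            best = res
        attempt += 1

    theta = np.asarray(best.x, dtype=float)
    converged = bool(best.success) and np.isfinite(best.fun) and best.fun < _PENALTY
    fml_val = float(best.fun)
    means = moments.mean  # profiled ML solution of the saturated means
    full = np.concatenate([means, theta])
    estimates = unpack_parameters(full, kind, T)

    sign, logdet_S = np.linalg.slogdet(moments.cov)
    p = 2 * T
    minus2 = N * (fml_val + logdet_S + p + p * math.log(2.0 * math.pi))

    fit = FitResult(
        kind=kind, estimates=estimates, minus2_loglik=minus2, fml=fml_val,
        se=np.full(k, np.nan), converged=converged,
        hessian_rcond=float("nan"), improper=False, improper_reason="none",
        k=k, N=N, T=T, aic=float("nan"), bic=float("nan"),
        n_fev=obj.n_fev, theta=theta,
    )

    # Hessian only when inference needs it or the variance check alone
    # cannot settle the improper classification.
    has_neg_var = any(v < 0 for v in _structural_variances(estimates, kind))
    if converged and (compute_se or not has_neg_var):
        H = _num_hessian(lambda x: obj.value_and_grad(x)[1], theta)
        fit.hessian_rcond = _hessian_rcond(H)
        if compute_se:
            fit.se = _se_from_hessian(fit, H, N)
    fit.improper, fit.improper_reason = classify_improper(
        fit, rcond_threshold, count_nonconvergence)
    fit.aic, fit.bic = information_criteria(fit)
    return fit


def fit_models(moments: MomentStructure, N: int,
               kinds: tuple = (ModelKind.CLPM, ModelKind.RI_CLPM, ModelKind.STARTS),
               *, warm_start: bool = True, **options) -> dict:
    """Fit several model kinds to the same moments.

    With ``warm_start`` (default), each richer model also starts from the
    best simpler solution with the added block at zero, which guarantees the
    nesting inequality -2lnL(CLPM) >= -2lnL(RI-CLPM) >= -2lnL(STARTS) up to
    optimizer tolerance.  Kinds infeasible at the available number of waves
    are skipped.
    """
    kinds = [ModelKind.coerce(knd) for knd in kinds]
    order = [knd for knd in (ModelKind.CLPM, ModelKind.RI_CLPM, ModelKind.STARTS)
             if knd in kinds]
    results: dict[ModelKind, FitResult] = {}
    prev_theta = None
    for knd in order:
        if moments.T < min_timepoints(knd):
            continue
        extra = ()
        if warm_start and prev_theta is not None:
            embedded = np.zeros(n_cov_parameters(knd))
            embedded[: prev_theta.shape[0]] = prev_theta
            extra = (embedded,)
        fit = fit_ml(moments, N, knd, extra_starts=extra, **options)
        results[knd] = fit
        if fit.theta is not None:
            prev_theta = fit.theta
    return results
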