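"""Parameter containers and the canonical parameter vector layout.

All moment-level code in this package shares one variable stacking order for
the observed vector at ``T`` occasions:

    (x_1, y_1, x_2, y_2, ..., x_T, y_T)

and one flat parameter ("pack") order per model kind:

    mu_x1, mu_y1, ..., mu_xT, mu_yT,          # 2T saturated temporal means
    beta_x, beta_y, gamma_x, gamma_y,         # lagged regression block
    omega2_x, omega2_y, omega_xy,             # residual (innovation) block
    init_var_x, init_var_y, init_cov,         # exogenous t=1 deviation block
    [trait_var_x, trait_var_y, trait_cov,]    # RI-CLPM and STARTS only
    [psi2_x, psi2_y, psi_xy,]                 # STARTS only

Variance entries are deliberately unconstrained: negative variance estimates
must remain representable because they are the primary signature of an
improper solution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelKind",
    "CrossLagParams",
    "MomentStructure",
    "free_parameter_count",
    "min_timepoints",
    "pack_parameters",
    "unpack_parameters",
]


class ModelKind(str, enum.Enum):
    """The three bivariate cross-lagged longitudinal models.

    ``CLPM``
        First-order bivariate autoregression on deviations from temporal
        group means. No trait factors, no measurement error.
    ``RI_CLPM``
        CLPM plus person-specific time-invariant trait factors (random
        intercepts) separating between-person from within-person variance.
    ``STARTS``
        RI-CLPM plus occasion-specific measurement error on every
        observation (stable trait + autoregressive trait + state).
    """

    CLPM = "clpm"
    RI_CLPM = "ri_clpm"
    STARTS = "starts"

    @property
    def has_trait(self) -> bool:
        return self is not ModelKind.CLPM

    @property
    def has_error(self) -> bool:
        return self is ModelKind.STARTS

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("-", "_")
        aliases = {"clpm": cls.CLPM, "ri_clpm": cls.RI_CLPM, "riclpm": cls.RI_CLPM,
                   "starts": cls.STARTS}
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown model kind: {value!r}") from None


#: minimum number of measurement occasions each model needs for identification
_MIN_T = {ModelKind.CLPM: 2, ModelKind.RI_CLPM: 3, ModelKind.STARTS: 4}


def min_timepoints(kind: ModelKind | str) -> int:
    """Minimum number of waves required to fit ``kind``."""
    return _MIN_T[ModelKind.coerce(kind)]


@dataclass
class CrossLagParams:
    """Full (time-invariant) parameter set of a bivariate cross-lagged model.

    Trait and measurement-error blocks are structurally zero for the kinds
    that exclude them; they are carried as plain zeros so that one container
    serves all three models.
    """

    beta_x: float = 0.0
    beta_y: float = 0.0
    gamma_x: float = 0.0
    gamma_y: float = 0.0
    omega2_x: float = 0.0
    omega2_y: float = 0.0
    omega_xy: float = 0.0
    init_var_x: float = 1.0
    init_var_y: float = 1.0
    init_cov: float = 0.0
    trait_var_x: float = 0.0
    trait_var_y: float = 0.0
    trait_cov: float = 0.0
    psi2_x: float = 0.0
    psi2_y: float = 0.0
    psi_xy: float = 0.0
    mu_x: np.ndarray = field(default_factory=lambda: np.zeros(2))
    mu_y: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.mu_x = np.asarray(self.mu_x, dtype=float)
        self.mu_y = np.asarray(self.mu_y, dtype=float)
        if self.mu_x.shape != self.mu_y.shape or self.mu_x.ndim != 1:
            raise ValueError("mu_x and mu_y must be 1-d sequences of equal length")

    @property
    def T(self) -> int:
        return self.mu_x.shape[0]

    # -- 2x2 parameter blocks ------------------------------------------------
    @property
    def B(self) -> np.ndarray:
        """Lagged coefficient matrix acting on the state (x*, y*)."""
        return np.array([[self.beta_x, self.gamma_x],
                         [self.gamma_y, self.beta_y]])

    @property
    def omega(self) -> np.ndarray:
        return np.array([[self.omega2_x, self.omega_xy],
                         [self.omega_xy, self.omega2_y]])

    @property
    def init_block(self) -> np.ndarray:
        return np.array([[self.init_var_x, self.init_cov],
                         [self.init_cov, self.init_var_y]])

    @property
    def trait_block(self) -> np.ndarray:
        return np.array([[self.trait_var_x, self.trait_cov],
                         [self.trait_cov, self.trait_var_y]])

    @property
    def error_block(self) -> np.ndarray:
        return np.array([[self.psi2_x, self.psi_xy],
                         [self.psi_xy, self.psi2_y]])

    def scalar_values(self) -> np.ndarray:
        """The 16 non-mean fields in pack order."""
        return np.array([
            self.beta_x, self.beta_y, self.gamma_x, self.gamma_y,
            self.omega2_x, self.omega2_y, self.omega_xy,
            self.init_var_x, self.init_var_y, self.init_cov,
            self.trait_var_x, self.trait_var_y, self.trait_cov,
            self.psi2_x, self.psi2_y, self.psi_xy,
        ])

    def structurally_consistent(self, kind: ModelKind) -> bool:
        """True if blocks that must be zero under ``kind`` are zero."""
        kind = ModelKind.coerce(kind)
        if not kind.has_trait and np.any(self.scalar_values()[10:13] != 0.0):
            return False
        if not kind.has_error and np.any(self.scalar_values()[13:16] != 0.0):
            return False
        return True

    def is_generation_legal(self, kind: ModelKind) -> bool:
        """Check positivity/correlation constraints needed to simulate data."""
        kind = ModelKind.coerce(kind)
        blocks = [self.omega, self.init_block]
        if kind.has_trait:
            blocks.append(self.trait_block)
        if kind.has_error:
            blocks.append(self.error_block)
        for blk in blocks:
            if not (blk[0, 0] > 0 and blk[1, 1] > 0):
                return False
            if blk[0, 1] ** 2 > blk[0, 0] * blk[1, 1]:
                return False
        return self.structurally_consistent(kind)

    def copy(self) -> "CrossLagParams":
        return replace(self, mu_x=self.mu_x.copy(), mu_y=self.mu_y.copy())


@dataclass
class MomentStructure:
    """First and second moments of the stacked observation vector.

    ``mean`` has length ``2T`` and ``cov`` shape ``(2T, 2T)`` in the canonical
    layout (x_1, y_1, ..., x_T, y_T).  Used both for model-implied moments and
    for the sufficient statistics of a sample (divisor-``N`` covariance).
    """

    mean: np.ndarray
    cov: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (2 * self.T,):
            raise ValueError("mean must have length 2*T")
        if self.cov.shape != (2 * self.T, 2 * self.T):
            raise ValueError("cov must be 2T x 2T")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")

    def block(self, t: int, u: int) -> np.ndarray:
        """The 2x2 covariance block of occasions ``t`` and ``u`` (1-based)."""
        i, j = 2 * (t - 1), 2 * (u - 1)
        return self.cov[i:i + 2, j:j + 2]


# number of free non-mean parameters per kind (time-invariance assumed)
_N_COV_PARAMS = {ModelKind.CLPM: 10, ModelKind.RI_CLPM: 13, ModelKind.STARTS: 16}


def n_cov_parameters(kind: ModelKind | str) -> int:
    """Free parameters excluding the 2T saturated means."""
    return _N_COV_PARAMS[ModelKind.coerce(kind)]


def free_parameter_count(kind: ModelKind | str, T: int) -> int:
    """Number of free parameters of ``kind`` with ``T`` occasions.

    Counts 2T saturated means, 4 lagged coefficients, 3 residual, 3 initial
    (co)variances, plus 3 trait and 3 error (co)variances where the model
    includes those blocks.
    """
    kind = ModelKind.coerce(kind)
    if T < min_timepoints(kind):
        raise ValueError(
            f"{kind.name} requires at least {min_timepoints(kind)} time points, got T={T}"
        )
    return 2 * T + n_cov_parameters(kind)


def pack_parameters(params: CrossLagParams, kind: ModelKind | str, T: int) -> np.ndarray:
    """Flatten ``params`` into the canonical vector for ``kind``."""
    kind = ModelKind.coerce(kind)
    if params.T != T:
        raise ValueError(f"params hold {params.T} means per variable, expected T={T}")
    means = np.column_stack([params.mu_x, params.mu_y]).ravel()
    vec = np.concatenate([means, params.scalar_values()[: n_cov_parameters(kind)]])
    if vec.shape[0] != free_parameter_count(kind, T):
        raise AssertionError("pack length mismatch")  # pragma: no cover
    return vec


def unpack_parameters(vector: np.ndarray, kind: ModelKind | str, T: int) -> CrossLagParams:
    """Inverse of :func:`pack_parameters`; never clamps out-of-range values."""
    kind = ModelKind.coerce(kind)
    vector = np.asarray(vector, dtype=float)
    k = free_parameter_count(kind, T)
    if vector.shape != (k,):
        raise ValueError(f"expected parameter vector of length {k}, got shape {vector.shape}")
    means = vector[: 2 * T].reshape(T, 2)
    scal = np.zeros(16)
    scal[: n_cov_parameters(kind)] = vector[2 * T:]
    return CrossLagParams(
        beta_x=scal[0], beta_y=scal[1], gamma_x=scal[2], gamma_y=scal[3],
        omega2_x=scal[4], omega2_y=scal[5], omega_xy=scal[6],
        init_var_x=scal[7], init_var_y=scal[8], init_cov=scal[9],
        trait_var_x=scal[10], trait_var_y=scal[11], trait_cov=scal[12],
        psi2_x=scal[13], psi2_y=scal[14], psi_xy=scal[15],
        mu_x=means[:, 0].copy(), mu_y=means[:, 1].copy(),
    )
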