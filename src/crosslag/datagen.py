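"""Synthetic bivariate longitudinal panels under the three generating models.

The default truth reproduces the simulation-study parameterization: temporal
group means mu_t = t - 1 for both variables, initial deviation variances
1 - psi^2, trait variances half the initial deviation variances, residual
variances 0.2, and every within-block correlation equal to 0.2.  Measurement
error variance psi^2 applies only when generating from the STARTS model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CrossLagParams, MomentStructure, ModelKind

__all__ = ["PanelDataset", "default_truth", "simulate_panel", "sample_moments",
           "write_panel", "read_panel"]

_CORR = 0.2  # common within-block correlation used throughout the studies


@dataclass
class PanelDataset:
    """An N x 2T complete bivariate panel with its generation provenance.

    ``data`` uses the canonical column layout (x_1, y_1, ..., x_T, y_T).
    """

    data: np.ndarray
    N: int
    T: int
    truth: CrossLagParams
    generation_kind: ModelKind
    seed: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.N, 2 * self.T):
            raise ValueError("data must be N x 2T in the canonical layout")
        if np.isnan(self.data).any():
            raise ValueError("panel data must be complete (no missing cells)")

    def to_frame(self) -> pd.DataFrame:
        """Wide data frame with columns x1..xT, y1..yT."""
        cols = [f"x{t}" for t in range(1, self.T + 1)] + \
               [f"y{t}" for t in range(1, self.T + 1)]
        x = self.data[:, 0::2]
        y = self.data[:, 1::2]
        return pd.DataFrame(np.hstack([x, y]), columns=cols)


def default_truth(kind: ModelKind | str, beta: float, gamma: float,
                  psi2: float = 0.0, T: int = 4) -> CrossLagParams:
    """Study parameterization of the generating model.

    ``psi2`` is forced to zero unless ``kind`` is STARTS.  All within-block
    correlations are 0.2; initial deviation variances are 1 - psi2 and trait
    variances half of that; residual variances 0.2; means mu_t = t - 1.
    """
    kind = ModelKind.coerce(kind)
    if not (math.isfinite(beta) and math.isfinite(gamma) and math.isfinite(psi2)):
        raise ValueError("beta, gamma and psi2 must be finite")
    psi2 = float(psi2) if kind.has_error else 0.0
    init_var = 1.0 - psi2
    trait_var = init_var / 2.0 if kind.has_trait else 0.0
    omega2 = 0.2
    mu = np.arange(T, dtype=float)  # t - 1
    return CrossLagParams(
        beta_x=beta, beta_y=beta, gamma_x=gamma, gamma_y=gamma,
        omega2_x=omega2, omega2_y=omega2, omega_xy=_CORR * omega2,
        init_var_x=init_var, init_var_y=init_var, init_cov=_CORR * init_var,
        trait_var_x=trait_var, trait_var_y=trait_var,
        trait_cov=_CORR * trait_var if kind.has_trait else 0.0,
        psi2_x=psi2, psi2_y=psi2, psi_xy=_CORR * psi2 if kind.has_error else 0.0,
        mu_x=mu.copy(), mu_y=mu.copy(),
    )


def _chol(block: np.ndarray, name: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(block)
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} block is not positive definite; "
                         "cannot generate data") from None


def simulate_panel(params: CrossLagParams, kind: ModelKind | str, N: int, T: int,
                   seed: int) -> PanelDataset:
    """Draw an N-person panel from the generative process of ``kind``.

    Each person receives (where the model includes them) a bivariate-normal
    trait pair, an initial deviation pair, innovations propagated through
    the lagged recursion for t >= 2, and occasion-specific measurement
    error.  Identical (params, kind, N, T, seed) give bit-identical data.
    """
    kind = ModelKind.coerce(kind)
    if N < 1:
        raise ValueError("N must be >= 1")
    if T < 2:
        raise ValueError("T must be >= 2")
    if params.T != T:
        raise ValueError("params.T does not match T")
    if not params.is_generation_legal(kind):
        raise ValueError("parameters are not legal for data generation "
                         f"under {kind.name}")

    rng = np.random.default_rng(seed)
    B = params.B
    L_init = _chol(params.init_block, "initial deviation")
    L_omega = _chol(params.omega, "residual")

    state = rng.standard_normal((N, 2)) @ L_init.T
    states = np.empty((N, T, 2))
    states[:, 0] = state
    for t in range(1, T):
        innov = rng.standard_normal((N, 2)) @ L_omega.T
        state = state @ B.T + innov
        states[:, t] = state

    obs = states
    if kind.has_trait:
        traits = rng.standard_normal((N, 2)) @ _chol(params.trait_block, "trait").T
        obs = obs + traits[:, None, :]
    if kind.has_error:
        errs = rng.standard_normal((N, T, 2)) @ _chol(params.error_block, "error").T
        obs = obs + errs
    mu = np.column_stack([params.mu_x, params.mu_y])  # (T, 2)
    data = (obs + mu[None, :, :]).reshape(N, 2 * T)
    return PanelDataset(data=data, N=N, T=T, truth=params.copy(),
                        generation_kind=kind, seed=int(seed))


def sample_moments(dataset: PanelDataset | np.ndarray, T: int | None = None) -> MomentStructure:
    """Sample mean vector and divisor-N covariance of a panel.

    The divisor-N (ML) convention makes the discrepancy function exactly
    zero when the implied moments coincide with the sample moments.
    """
    if isinstance(dataset, PanelDataset):
        data, T = dataset.data, dataset.T
    else:
        data = np.asarray(dataset, dtype=float)
        if T is None:
            raise ValueError("T is required when passing a bare matrix")
    n = data.shape[0]
    if n < 2:
        raise ValueError("sample moments require at least two individuals")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / n
    return MomentStructure(mean=mean, cov=0.5 * (cov + cov.T), T=int(T))


# ---------------------------------------------------------------------------
# delimited-text round trip (CSV data + JSON provenance sidecar)

def write_panel(dataset: PanelDataset, path: str | Path) -> Path:
    """Write the panel as CSV (columns x1..xT,y1..yT) plus a JSON sidecar.

    Values serialize at full round-trip precision; the sidecar records the
    truth parameters, generating kind and seed.
    """
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    truth = asdict(dataset.truth)
    truth["mu_x"] = dataset.truth.mu_x.tolist()
    truth["mu_y"] = dataset.truth.mu_y.tolist()
    meta = {"N": dataset.N, "T": dataset.T, "seed": dataset.seed,
            "generation_kind": dataset.generation_kind.value, "truth": truth}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_panel(path: str | Path) -> PanelDataset:
    """Read a panel written by :func:`write_panel` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    xcols = sorted((c for c in df.columns if c[0] == "x" and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    ycols = sorted((c for c in df.columns if c[0] == "y" and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    if not xcols or len(xcols) != len(ycols):
        bad = [c for c in df.columns if c not in xcols + ycols]
        raise ValueError(
            "expected matched columns x1..xT and y1..yT; offending columns: "
            f"{bad or df.columns.tolist()}")
    T = len(xcols)
    data = np.empty((len(df), 2 * T))
    data[:, 0::2] = df[xcols].to_numpy(float)
    data[:, 1::2] = df[ycols].to_numpy(float)

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        truth = CrossLagParams(**meta["truth"])
        kind = ModelKind.coerce(meta["generation_kind"])
        seed = int(meta["seed"])
    else:
        truth = CrossLagParams(mu_x=np.zeros(T), mu_y=np.zeros(T))
        kind = ModelKind.CLPM
        seed = -1
    return PanelDataset(data=data, N=len(df), T=T, truth=truth,
                        generation_kind=kind, seed=seed)
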