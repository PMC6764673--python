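"""Model / results interface in the style of statsmodels.

``CrossLagModel`` is built from a panel (array, DataFrame or
:class:`~crosslag.datagen.PanelDataset`) or directly from sample moments;
``fit`` returns a :class:`CrossLagResults` carrying estimates, standard
errors, diagnostics and a text ``summary`` table.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import estimation
from .datagen import PanelDataset, sample_moments
from .estimation import (FitResult, fit_indices, fit_ml, start_values,
                         wald_significance)
from .params import (MomentStructure, ModelKind, free_parameter_count,
                     min_timepoints, n_cov_parameters)

__all__ = ["CrossLagModel", "CrossLagResults"]

_PARAM_NAMES = [
    "beta_x", "beta_y", "gamma_x", "gamma_y",
    "omega2_x", "omega2_y", "omega_xy",
    "init_var_x", "init_var_y", "init_cov",
    "trait_var_x", "trait_var_y", "trait_cov",
    "psi2_x", "psi2_y", "psi_xy",
]


class CrossLagModel:
    """A cross-lagged longitudinal model bound to one bivariate panel.

    Parameters
    ----------
    data
        ``PanelDataset``, wide ``DataFrame`` with columns ``x1..xT,y1..yT``,
        or an ``(N, 2T)`` array in the canonical interleaved layout.
    kind
        ``"clpm"``, ``"ri_clpm"`` or ``"starts"``.

    Examples
    --------
    >>> from crosslag import CrossLagModel, default_truth, simulate_panel
    >>> panel = simulate_panel(default_truth("clpm", 0.5, 0.2, T=4),
    ...                        "clpm", N=500, T=4, seed=7)
    >>> res = CrossLagModel(panel, "clpm").fit()
    >>> bool(res.converged)
    True
    """

    def __init__(self, data, kind: ModelKind | str, T: int | None = None):
        self.kind = ModelKind.coerce(kind)
        if isinstance(data, MomentStructure):
            raise TypeError("use CrossLagModel.from_moments for moment input")
        if isinstance(data, PanelDataset):
            self.moments = sample_moments(data)
            self.nobs = data.N
        elif isinstance(data, pd.DataFrame):
            mat, T = _frame_to_matrix(data)
            self.moments = sample_moments(mat, T)
            self.nobs = mat.shape[0]
        else:
            mat = np.asarray(data, dtype=float)
            if T is None:
                if mat.shape[1] % 2:
                    raise ValueError("array input needs an even column count")
                T = mat.shape[1] // 2
            self.moments = sample_moments(mat, T)
            self.nobs = mat.shape[0]
        if self.moments.T < min_timepoints(self.kind):
            raise ValueError(
                f"{self.kind.name} requires at least {min_timepoints(self.kind)} "
                f"time points; data have T={self.moments.T}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: ModelKind | str) -> "CrossLagModel":
        return cls(df, kind)

    @classmethod
    def from_moments(cls, moments: MomentStructure, nobs: int,
                     kind: ModelKind | str) -> "CrossLagModel":
        obj = cls.__new__(cls)
        obj.kind = ModelKind.coerce(kind)
        obj.moments = moments
        obj.nobs = int(nobs)
        return obj

    @property
    def T(self) -> int:
        return self.moments.T

    def start_params(self) -> np.ndarray:
        return start_values(self.moments, self.kind)

    def fit(self, **options) -> "CrossLagResults":
        raw = fit_ml(self.moments, self.nobs, self.kind, **options)
        return CrossLagResults(self, raw)


class CrossLagResults:
    """Estimates, uncertainties and diagnostics of one fitted model."""

    def __init__(self, model: CrossLagModel, raw: FitResult):
        self.model = model
        self.raw = raw

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def params(self):
        return self.raw.estimates

    @property
    def packed(self) -> np.ndarray:
        return self.raw.packed

    @property
    def bse(self) -> np.ndarray:
        return self.raw.se

    @property
    def llf(self) -> float:
        return -0.5 * self.raw.minus2_loglik

    @property
    def aic(self) -> float:
        return self.raw.aic

    @property
    def bic(self) -> float:
        return self.raw.bic

    @property
    def fml(self) -> float:
        return self.raw.fml

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def improper(self) -> bool:
        return self.raw.improper

    @property
    def improper_reason(self) -> str:
        return self.raw.improper_reason

    @property
    def df_model(self) -> int:
        return self.raw.k

    def param_table(self) -> pd.DataFrame:
        """Non-mean parameters with estimates and standard errors."""
        T = self.raw.T
        names = _PARAM_NAMES[: n_cov_parameters(self.raw.kind)]
        est = self.params.scalar_values()[: len(names)]
        se = self.raw.se[2 * T:]
        return pd.DataFrame({"Est.": est, "SE": se}, index=names)

    def wald_cross_lagged(self, alpha: float = 0.05) -> dict:
        """Two-sided Wald tests of the cross-lagged coefficients."""
        T = self.raw.T
        idx = {"gamma_x": 2 * T + 2, "gamma_y": 2 * T + 3}
        packed = self.packed
        return {name: wald_significance(packed[i], self.raw.se[i], alpha)
                for name, i in idx.items()}

    def fit_indices(self) -> tuple[float, float, float]:
        """(RMSEA, CFI, SRMR)."""
        return fit_indices(self.raw, self.model.moments, self.raw.N)

    def summary(self) -> str:
        """Human-readable fit report (Est./SE per parameter, fit footer)."""
        r = self.raw
        lines = [
            f"Cross-lagged model fit: {r.kind.name}",
            f"  N = {r.N}, T = {r.T}, free parameters k = {r.k}",
            f"  converged = {r.converged}, improper = {r.improper}"
            + (f" ({r.improper_reason})" if r.improper else ""),
            "",
            f"  {'parameter':<14}{'Est.':>10}{'SE':>10}",
        ]
        tbl = self.param_table()
        for name, row in tbl.iterrows():
            se = f"{row['SE']:.4f}" if np.isfinite(row["SE"]) else "--"
            lines.append(f"  {name:<14}{row['Est.']:>10.4f}{se:>10}")
        mu = self.params
        lines.append("")
        lines.append("  temporal means mu_x: "
                     + " ".join(f"{v:.3f}" for v in mu.mu_x))
        lines.append("  temporal means mu_y: "
                     + " ".join(f"{v:.3f}" for v in mu.mu_y))
        lines.append("")
        lines.append(f"  -2lnL = {r.minus2_loglik:.3f}   F_ML = {r.fml:.6f}")
        lines.append(f"  AIC = {r.aic:.3f}   BIC = {r.bic:.3f}")
        if r.converged:
            rmsea, cfi, srmr = self.fit_indices()
            lines.append(f"  RMSEA = {rmsea:.4f}   CFI = {cfi:.4f}   SRMR = {srmr:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        r = self.raw
        return {
            "kind": r.kind.value, "N": r.N, "T": r.T, "k": r.k,
            "converged": r.converged, "improper": r.improper,
            "improper_reason": r.improper_reason,
            "minus2_loglik": r.minus2_loglik, "fml": r.fml,
            "aic": r.aic, "bic": r.bic,
            "hessian_rcond": r.hessian_rcond,
            "packed": [None if not np.isfinite(v) else float(v)
                       for v in r.packed],
            "se": [None if not np.isfinite(v) else float(v) for v in r.se],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _frame_to_matrix(df: pd.DataFrame):
    xcols = sorted((c for c in df.columns if str(c)[0] == "x" and str(c)[1:].isdigit()),
                   key=lambda c: int(str(c)[1:]))
    ycols = sorted((c for c in df.columns if str(c)[0] == "y" and str(c)[1:].isdigit()),
                   key=lambda c: int(str(c)[1:]))
    if not xcols or len(xcols) != len(ycols):
        raise ValueError("DataFrame must carry matched columns x1..xT and y1..yT")
    T = len(xcols)
    mat = np.empty((len(df), 2 * T))
    mat[:, 0::2] = df[xcols].to_numpy(float)
    mat[:, 1::2] = df[ycols].to_numpy(float)
    return mat, T
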