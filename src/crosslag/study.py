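"""Monte Carlo study drivers: improper-solution frequency and estimate properties.

Study 1 crosses a generation-model grid (sample size, waves, autoregression,
and — for STARTS generation — measurement-error variance) with the three
analysis models and records how often each analysis model terminates in an
improper solution.  Study 2 re-draws datasets, discarding any draw on which
a requested analysis model is improper or nonconvergent, until a target
number of clean trials accrues per condition, and summarizes standard
errors of the cross-lagged estimates, pairwise significance agreement, and
information-criterion preferences.

Reproducibility: every trial's seed derives deterministically from the
master seed, the condition index and the draw index, so results are
bit-identical regardless of execution order or parallelism.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datagen import default_truth, sample_moments, simulate_panel
from .estimation import fit_ml, fit_models
from .params import ModelKind, min_timepoints

__all__ = ["StudyCondition", "MarginalTable", "build_conditions",
           "run_improper_study", "run_estimates_study", "marginalize",
           "STUDY1_DEFAULTS", "STUDY2_DEFAULTS", "FACTORS",
           "ImproperStudyResult", "EstimatesStudyResult"]

log = logging.getLogger("crosslag.study")

FACTORS = ("beta", "gamma", "psi2", "N", "T")

#: factor levels of the improper-solution study
STUDY1_DEFAULTS = dict(N=(200, 600, 1000), T=(4, 6, 8), beta=(0.5, 0.7, 0.9),
                       gamma=(0.2,), psi2=(0.2, 0.5, 0.8), trials=200)
#: factor levels of the estimate-properties study
STUDY2_DEFAULTS = dict(N=(200, 600, 1000), T=(4, 6, 8), beta=(0.5, 0.7),
                       gamma=(0.0, 0.1, 0.2), psi2=(0.2, 0.4, 0.6), trials=100)


@dataclass(frozen=True)
class StudyCondition:
    """One cell of a simulation grid (generation side)."""

    generation_kind: ModelKind
    N: int
    T: int
    beta: float
    gamma: float
    psi2: float
    trials: int

    def truth(self):
        return default_truth(self.generation_kind, self.beta, self.gamma,
                             self.psi2, T=self.T)


@dataclass
class MarginalTable:
    """Cell statistics at each level of one design factor.

    ``table`` is indexed by factor level; columns are analysis kinds (or
    category labels), values are means over all conditions sharing the
    level (equal condition weighting).
    """

    factor: str
    stat: str
    table: pd.DataFrame


def build_conditions(generation_kind: ModelKind | str,
                     N=None, T=None, beta=None, gamma=None, psi2=None,
                     trials: int | None = None,
                     defaults: dict = STUDY1_DEFAULTS) -> list[StudyCondition]:
    """Full factorial grid of conditions for one generation model.

    The measurement-error factor ``psi2`` is crossed only when generating
    from STARTS; for the other generation models it is pinned at zero.
    """
    kind = ModelKind.coerce(generation_kind)
    N = tuple(defaults["N"] if N is None else N)
    T = tuple(defaults["T"] if T is None else T)
    beta = tuple(defaults["beta"] if beta is None else beta)
    gamma = tuple(defaults["gamma"] if gamma is None else
                  (gamma if np.iterable(gamma) else (gamma,)))
    psi2 = tuple(defaults["psi2"] if psi2 is None else psi2) if kind.has_error else (0.0,)
    trials = defaults["trials"] if trials is None else int(trials)
    for name, levels in (("N", N), ("T", T), ("beta", beta), ("gamma", gamma),
                         ("psi2", psi2)):
        if len(levels) == 0:
            raise ValueError(f"factor {name} has no levels")
    return [StudyCondition(kind, n, t, b, g, p, trials)
            for b, g, p, n, t in itertools.product(beta, gamma, psi2, N, T)]


def trial_seed(master_seed: int, cond_index: int, draw_index: int) -> int:
    """Deterministic per-draw seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(int(cond_index), int(draw_index)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _cond_columns(cond: StudyCondition, ci: int) -> dict:
    return {"cond": ci, "generation": cond.generation_kind.value,
            "N": cond.N, "T": cond.T, "beta": cond.beta,
            "gamma": cond.gamma, "psi2": cond.psi2}


# ---------------------------------------------------------------------------
# study 1: frequency of improper solutions

@dataclass
class ImproperStudyResult:
    raw: pd.DataFrame
    conditions: list[StudyCondition]

    def marginal(self, factor: str) -> MarginalTable:
        return marginalize(self.raw, factor, values=("improper",))

    def marginals(self) -> dict:
        present = [f for f in FACTORS if self.raw[f].nunique() > 1] or ["N"]
        return {f: self.marginal(f) for f in present}

    def aggregate(self) -> pd.Series:
        """Overall improper proportion per analysis kind (conditions equally weighted)."""
        if self.raw.empty:
            return pd.Series(dtype=float)
        percond = (self.raw.groupby(["analysis", "cond"])["improper"]
                   .mean().reset_index())
        return percond.groupby("analysis")["improper"].mean()


def _improper_condition(cond: StudyCondition, ci: int, analysis_kinds,
                        master_seed: int, rcond_threshold: float,
                        count_nonconvergence: bool) -> list[dict]:
    rows = []
    truth = cond.truth()
    feasible = [a for a in analysis_kinds if cond.T >= min_timepoints(a)]
    for ti in range(cond.trials):
        seed = trial_seed(master_seed, ci, ti)
        panel = simulate_panel(truth, cond.generation_kind, cond.N, cond.T, seed)
        moments = sample_moments(panel)
        base = _cond_columns(cond, ci)
        for a in analysis_kinds:
            row = dict(base, trial=ti, seed=seed, analysis=a.value)
            if a not in feasible:
                row.update(feasible_fit=False, converged=np.nan,
                           improper=np.nan, reason="not_applicable",
                           fml=np.nan)
            else:
                fit = fit_ml(moments, cond.N, a, compute_se=False,
                             rcond_threshold=rcond_threshold,
                             count_nonconvergence=count_nonconvergence)
                row.update(feasible_fit=True, converged=float(fit.converged),
                           improper=float(fit.improper),
                           reason=fit.improper_reason, fml=fit.fml)
                log.debug("cond=%d trial=%d kind=%s converged=%s reason=%s "
                          "fml=%.6g", ci, ti, a.value, fit.converged,
                          fit.improper_reason, fit.fml)
            rows.append(row)
    return rows


def run_improper_study(conditions: list[StudyCondition], analysis_kinds,
                       seed: int, *, rcond_threshold: float = 1e-10,
                       count_nonconvergence: bool = False,
                       n_jobs: int = 1,
                       progress=None) -> ImproperStudyResult:
    """Simulate every condition and count improper solutions per analysis model.

    Each analysis model is fitted independently (its own moment-based
    start), mirroring how the models would be fitted one at a time in
    practice.  An analysis kind whose minimum number of waves exceeds a
    condition's ``T`` is recorded as not applicable, never as zero.
    """
    analysis_kinds = [ModelKind.coerce(a) for a in analysis_kinds]
    args = [(cond, ci, analysis_kinds, seed, rcond_threshold,
             count_nonconvergence) for ci, cond in enumerate(conditions)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_improper_condition)(*a) for a in args)
    else:
        chunks = []
        for a in args:
            chunks.append(_improper_condition(*a))
            if progress is not None:
                progress(a[1] + 1, len(args))
    rows = [r for chunk in chunks for r in chunk]
    columns = ["cond", "generation", "N", "T", "beta", "gamma", "psi2",
               "trial", "seed", "analysis", "feasible_fit", "converged",
               "improper", "reason", "fml"]
    raw = pd.DataFrame(rows, columns=columns)
    return ImproperStudyResult(raw=raw, conditions=list(conditions))


# ---------------------------------------------------------------------------
# study 2: statistical properties of estimates on clean trials

AGREEMENT_CATEGORIES = ("both_nonsig", "first_only", "second_only", "both_sig")


@dataclass
class EstimatesStudyResult:
    raw: pd.DataFrame                    # one row per trial x analysis kind
    condition_log: pd.DataFrame          # achieved trials, draws used, cap flag
    conditions: list[StudyCondition]
    analysis_kinds: list[ModelKind] = field(default_factory=list)

    def se_marginal(self, factor: str) -> MarginalTable:
        """Marginal means of the cross-lagged SE (gamma_x and gamma_y averaged)."""
        raw = self.raw.copy()
        raw["se_gamma"] = 0.5 * (raw["se_gx"] + raw["se_gy"])
        tab = marginalize(raw, factor, values=("se_gamma",))
        tab.stat = "mean_se_gamma"
        return tab

    def agreement_marginal(self, pair, factor: str) -> MarginalTable:
        """Four-way significance agreement for an ordered model pair.

        Each clean trial contributes one comparison per cross-lagged
        parameter (gamma_x and gamma_y), categorized by which of the two
        models calls it significant.
        """
        k1, k2 = (ModelKind.coerce(k) for k in pair)
        w = self.raw.pivot_table(index=["cond", "trial"] + list(FACTORS),
                                 columns="analysis",
                                 values=["sig_gx", "sig_gy"])
        rows = []
        for key, r in w.iterrows():
            rec = dict(zip(["cond", "trial"] + list(FACTORS), key))
            for par in ("sig_gx", "sig_gy"):
                s1 = bool(r[(par, k1.value)])
                s2 = bool(r[(par, k2.value)])
                cat = AGREEMENT_CATEGORIES[(2 if s1 else 0) + (1 if s2 else 0)]
                rows.append(dict(rec, **{c: float(c == cat)
                                         for c in AGREEMENT_CATEGORIES}))
        flat = pd.DataFrame(rows)
        flat["analysis"] = f"{k1.value}_vs_{k2.value}"
        tab = marginalize(flat, factor, values=AGREEMENT_CATEGORIES)
        tab.stat = f"significance_agreement:{k1.value}_vs_{k2.value}"
        return tab

    def ic_preference_marginal(self, criterion: str, factor: str) -> MarginalTable:
        """Proportion of trials on which each model has the lowest AIC or BIC."""
        if criterion not in ("aic", "bic"):
            raise ValueError("criterion must be 'aic' or 'bic'")
        w = self.raw.pivot_table(index=["cond", "trial"] + list(FACTORS),
                                 columns="analysis", values=criterion)
        kinds = [k.value for k in self.analysis_kinds]
        best = w[kinds].idxmin(axis=1)
        flat = best.reset_index(name="preferred")
        for k in kinds:
            flat[k] = (flat["preferred"] == k).astype(float)
        flat["analysis"] = criterion
        tab = marginalize(flat, factor, values=tuple(kinds))
        tab.stat = f"{criterion}_preference"
        return tab


def _estimates_condition(cond: StudyCondition, ci: int, analysis_kinds,
                         master_seed: int, alpha: float,
                         rcond_threshold: float, redraw_cap: int):
    feasible = [a for a in analysis_kinds if cond.T >= min_timepoints(a)]
    truth = cond.truth()
    rows, successes, draw = [], 0, 0
    while successes < cond.trials and draw < redraw_cap:
        seed = trial_seed(master_seed, ci, draw)
        draw += 1
        panel = simulate_panel(truth, cond.generation_kind, cond.N, cond.T, seed)
        moments = sample_moments(panel)
        fits = fit_models(moments, cond.N, feasible,
                          rcond_threshold=rcond_threshold)
        clean = all(f.converged and not f.improper for f in fits.values())
        if clean:
            # the paired significance tables additionally need testable SEs
            for f in fits.values():
                se = f.se[2 * cond.T + 2: 2 * cond.T + 4]
                if not np.all(np.isfinite(se)) or np.any(se <= 0):
                    clean = False
        if not clean:
            continue
        base = _cond_columns(cond, ci)
        for a, f in fits.items():
            packed = f.packed
            i = 2 * cond.T
            gx, gy = packed[i + 2], packed[i + 3]
            se_gx, se_gy = f.se[i + 2], f.se[i + 3]
            zx = abs(gx / se_gx)
            zy = abs(gy / se_gy)
            rows.append(dict(
                base, trial=successes, seed=seed, analysis=a.value,
                gx=gx, gy=gy, se_gx=se_gx, se_gy=se_gy,
                sig_gx=float(2 * norm.sf(zx) < alpha),
                sig_gy=float(2 * norm.sf(zy) < alpha),
                aic=f.aic, bic=f.bic, fml=f.fml,
            ))
        successes += 1
    log = dict(_cond_columns(cond, ci), requested=cond.trials,
               achieved=successes, draws=draw, cap_hit=successes < cond.trials)
    return rows, log


def run_estimates_study(conditions: list[StudyCondition], analysis_kinds,
                        seed: int, *, alpha: float = 0.05,
                        rcond_threshold: float = 1e-10,
                        redraw_cap_factor: int = 50,
                        n_jobs: int = 1,
                        progress=None) -> EstimatesStudyResult:
    """Run the estimate-properties study with discard-and-retry sampling.

    A draw is retained only when every requested (and feasible) analysis
    model converges with a proper solution on that dataset, so the pairwise
    agreement tables compare fits on identical data.  A condition stops
    early — flagged, never padded — after ``redraw_cap_factor * trials``
    draws.
    """
    analysis_kinds = [ModelKind.coerce(a) for a in analysis_kinds]
    args = [(cond, ci, analysis_kinds, seed, alpha, rcond_threshold,
             redraw_cap_factor * cond.trials)
            for ci, cond in enumerate(conditions)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        out = Parallel(n_jobs=n_jobs)(
            delayed(_estimates_condition)(*a) for a in args)
    else:
        out = []
        for a in args:
            out.append(_estimates_condition(*a))
            if progress is not None:
                progress(a[1] + 1, len(args))
    rows = [r for chunk, _ in out for r in chunk]
    logs = [log for _, log in out]
    columns = ["cond", "generation", "N", "T", "beta", "gamma", "psi2",
               "trial", "seed", "analysis", "gx", "gy", "se_gx", "se_gy",
               "sig_gx", "sig_gy", "aic", "bic", "fml"]
    raw = pd.DataFrame(rows, columns=columns)
    return EstimatesStudyResult(raw=raw, condition_log=pd.DataFrame(logs),
                                conditions=list(conditions),
                                analysis_kinds=analysis_kinds)


# ---------------------------------------------------------------------------

def marginalize(raw: pd.DataFrame, factor: str,
                values: tuple = ("improper",),
                by: str = "analysis") -> MarginalTable:
    """Average per-condition cell statistics at each level of a factor.

    Conditions are weighted equally (a condition's trials are first averaged
    within the condition), matching marginal means aggregated across all the
    other factors.  Cells with no feasible trials stay NaN.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    values = list(values)
    if raw.empty:
        return MarginalTable(factor=factor, stat=",".join(values),
                             table=pd.DataFrame())
    percond = raw.groupby([by, "cond", factor], dropna=False)[values].mean().reset_index()
    marg = percond.groupby([by, factor])[values].mean().reset_index()
    if len(values) == 1:
        table = marg.pivot(index=factor, columns=by, values=values[0])
    else:
        table = marg.set_index([factor, by])[values].unstack(by) \
            if marg[by].nunique() > 1 else marg.set_index(factor)[values]
    return MarginalTable(factor=factor, stat=",".join(values), table=table)
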