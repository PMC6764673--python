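import math

import numpy as np
import pytest

from crosslag import (FitResult, ModelKind, classify_improper, default_truth,
                      fit_indices, fit_ml, fit_models, fml, implied_moments,
                      information_criteria, pack_parameters, sample_moments,
                      simulate_panel, standard_errors, start_values,
                      wald_significance)
from crosslag.datagen import PanelDataset
from crosslag.params import MomentStructure, free_parameter_count


@pytest.mark.parametrize("kind,psi2", [("clpm", 0.0), ("ri_clpm", 0.0),
                                       ("starts", 0.2)])
def test_zero_discrepancy_recovery(kind, psi2):
    """Fitting the model to its own implied moments returns the truth."""
    truth = default_truth(kind, 0.5, 0.2, psi2, T=4)
    moments = implied_moments(truth, 4, kind)
    fit = fit_ml(moments, 1000, kind)
    assert fit.converged and not fit.improper
    assert fit.fml == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(fit.packed, pack_parameters(truth, kind, 4), atol=1e-5)
    # regular interior optimum: every standard error finite and positive
    assert np.all(np.isfinite(fit.se)) and np.all(fit.se > 0)


def test_fml_zero_iff_moments_match():
    truth = default_truth("clpm", 0.5, 0.2, T=4)
    m = implied_moments(truth, 4, "clpm")
    assert fml(truth, m, "clpm") == pytest.approx(0.0, abs=1e-12)
    shifted = truth.copy()
    shifted.mu_x = shifted.mu_x + 0.5
    assert fml(shifted, m, "clpm") > 0.01


def test_consistency_large_n_clpm():
    """gamma estimates land within 3 reported SEs of the truth at large N."""
    truth = default_truth("clpm", 0.5, 0.2, T=6)
    panel = simulate_panel(truth, "clpm", 100_000, 6, seed=77)
    fit = fit_ml(sample_moments(panel), panel.N, "clpm")
    i = 2 * 6
    for slot in (i + 2, i + 3):   # gamma_x, gamma_y
        assert abs(fit.packed[slot] - 0.2) < 3 * fit.se[slot]


def test_likelihood_nesting_with_warm_starts(clpm_panel_moments, clpm_panel):
    fits = fit_models(clpm_panel_moments, clpm_panel.N)
    m2 = {k: f.minus2_loglik for k, f in fits.items()}
    assert m2[ModelKind.CLPM] >= m2[ModelKind.RI_CLPM] - 1e-6
    assert m2[ModelKind.RI_CLPM] >= m2[ModelKind.STARTS] - 1e-6


class TestStartValues:
    def test_zero_coefficient_moments_give_near_zero_start(self):
        truth = default_truth("clpm", 0.0, 0.0, T=4)
        truth.beta_x = truth.beta_y = 0.0
        m = implied_moments(truth, 4, "clpm")
        vec = start_values(m, "clpm")
        assert np.all(np.abs(vec[8:12]) < 0.05)  # beta/gamma slots at T=4

    def test_degenerate_identical_columns_finite(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=(40, 1))
        panel = np.hstack([col, col, col, col, col, col, col, col])
        m = sample_moments(panel, T=4)
        for kind in ModelKind:
            assert np.all(np.isfinite(start_values(m, kind)))

    def test_constant_data_finite(self):
        panel = np.ones((30, 8))
        panel[0] += 1e-9  # avoid an exactly singular sample covariance
        m = sample_moments(panel, T=4)
        vec = start_values(m, "starts")
        assert np.all(np.isfinite(vec))


class TestStandardErrors:
    def test_scaling_with_sample_size(self):
        """Median SE shrinks about as 1/sqrt(N) when N doubles."""
        truth = default_truth("clpm", 0.5, 0.2, T=4)
        med = {}
        for N in (400, 800):
            ses = []
            for rep in range(30):
                panel = simulate_panel(truth, "clpm", N, 4, seed=10_000 + rep + N)
                fit = fit_ml(sample_moments(panel), N, "clpm")
                ses.append(fit.se[2 * 4 + 2])
            med[N] = np.median(ses)
        ratio = med[800] / med[400]
        assert ratio == pytest.approx(1 / math.sqrt(2), rel=0.15)

    def test_standalone_recomputation_matches(self, clpm_panel_moments, clpm_panel):
        fit = fit_ml(clpm_panel_moments, clpm_panel.N, "clpm")
        se = standard_errors(fit, clpm_panel_moments, clpm_panel.N)
        assert np.allclose(se, fit.se, rtol=1e-4, equal_nan=True)

    def test_requires_convergence(self, clpm_panel_moments, clpm_panel):
        fit = fit_ml(clpm_panel_moments, clpm_panel.N, "clpm")
        fit.converged = False
        with pytest.raises(ValueError):
            standard_errors(fit, clpm_panel_moments, clpm_panel.N)


def _dummy_fit(kind=ModelKind.RI_CLPM, rcond=1e-3, **overrides):
    truth = default_truth(kind, 0.5, 0.2, 0.2, T=4)
    for name, val in overrides.items():
        setattr(truth, name, val)
    k = free_parameter_count(kind, 4)
    return FitResult(kind=kind, estimates=truth, minus2_loglik=0.0, fml=0.0,
                     se=np.ones(k), converged=True, hessian_rcond=rcond,
                     improper=False, improper_reason="none", k=k, N=100, T=4,
                     aic=0.0, bic=0.0)


class TestClassifyImproper:
    def test_negative_trait_variance(self):
        fit = _dummy_fit(trait_var_x=-0.01)
        assert classify_improper(fit) == (True, "negative_variance")

    def test_healthy_fit_with_moderate_rcond(self):
        fit = _dummy_fit(rcond=1e-3)
        assert classify_improper(fit) == (False, "none")

    def test_singular_hessian(self):
        fit = _dummy_fit(rcond=1e-12)
        assert classify_improper(fit) == (True, "singular_hessian")

    def test_out_of_range_correlation(self):
        fit = _dummy_fit(omega_xy=0.5)   # |r| > 1 given omega2 = 0.2
        improper, reason = classify_improper(fit)
        assert improper and reason == "negative_variance"

    def test_negative_variance_takes_precedence(self):
        fit = _dummy_fit(rcond=1e-12, psi2_x=-0.2, kind=ModelKind.STARTS)
        assert classify_improper(fit) == (True, "negative_variance")

    def test_nonconvergence_optional(self):
        fit = _dummy_fit()
        fit.converged = False
        assert classify_improper(fit) == (False, "none")
        assert classify_improper(fit, count_nonconvergence=True) == \
            (True, "nonconvergence")

    def test_deterministic(self):
        fit = _dummy_fit(trait_var_y=-0.5)
        assert classify_improper(fit) == classify_improper(fit)


def test_misspecified_starts_mostly_improper():
    """STARTS fitted to CLPM-generated panels is improper in most trials."""
    truth = default_truth("clpm", 0.7, 0.2, T=6)
    improper = 0
    n_trials = 12
    for s in range(n_trials):
        panel = simulate_panel(truth, "clpm", 600, 6, seed=40_000 + s)
        fit = fit_ml(sample_moments(panel), 600, "starts", compute_se=False)
        improper += fit.improper
    assert improper / n_trials >= 0.75


def test_clpm_gamma_se_magnitude_large_n():
    """At N=1000, T=8 the cross-lagged SE of a well-specified CLPM is ~0.01."""
    ses = []
    for beta, seed in ((0.5, 1), (0.7, 2)):
        truth = default_truth("clpm", beta, 0.2, T=8)
        panel = simulate_panel(truth, "clpm", 1000, 8, seed=seed)
        fit = fit_ml(sample_moments(panel), 1000, "clpm")
        ses += [fit.se[2 * 8 + 2], fit.se[2 * 8 + 3]]
    assert 0.005 < np.mean(ses) < 0.02


class TestWald:
    def test_basic_arithmetic(self):
        w = wald_significance(0.2, 0.1, 0.05)
        assert w.z == pytest.approx(2.0)
        assert w.p == pytest.approx(0.0455, abs=1e-3)
        assert w.significant is True

    def test_zero_estimate(self):
        w = wald_significance(0.0, 0.1, 0.05)
        assert w.z == 0 and w.p == pytest.approx(1.0)
        assert w.significant is False

    def test_boundary_at_normal_quantile(self):
        # the exact two-sided 5% boundary is z = 1.959964; at the boundary
        # p equals alpha and the test is not significant (p < alpha strict)
        from scipy.stats import norm
        zc = norm.ppf(0.975)
        assert zc == pytest.approx(1.959964, abs=1e-6)
        assert wald_significance(zc * 0.1, 0.1, 0.05).significant is False
        assert wald_significance((zc + 1e-6) * 0.1, 0.1, 0.05).significant is True

    def test_untestable_se(self):
        assert wald_significance(0.2, 0.0, 0.05).significant is None
        assert wald_significance(0.2, np.nan, 0.05).significant is None


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        fit = _dummy_fit(kind=ModelKind.CLPM)
        fit.minus2_loglik, fit.k, fit.N = 200.0, 18, 100
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(236.0)
        assert bic == pytest.approx(200 + 18 * math.log(100), abs=1e-6)

    def test_bic_aic_identity(self, clpm_panel_moments, clpm_panel):
        for kind in ("clpm", "ri_clpm", "starts"):
            fit = fit_ml(clpm_panel_moments, clpm_panel.N, kind, compute_se=False)
            assert fit.bic - fit.aic == pytest.approx(
                fit.k * (math.log(fit.N) - 2), rel=1e-12)


class TestFitIndices:
    def test_perfect_fit(self):
        truth = default_truth("ri_clpm", 0.5, 0.2, T=4)
        m = implied_moments(truth, 4, "ri_clpm")
        fit = fit_ml(m, 500, "ri_clpm")
        rmsea, cfi, srmr = fit_indices(fit, m, 500)
        assert rmsea == pytest.approx(0.0, abs=1e-4)
        assert cfi == pytest.approx(1.0, abs=1e-4)
        assert srmr == pytest.approx(0.0, abs=1e-4)

    def test_srmr_scale_invariance(self, clpm_panel):
        m1 = sample_moments(clpm_panel)
        fit1 = fit_ml(m1, clpm_panel.N, "clpm", compute_se=False)
        scaled = PanelDataset(data=clpm_panel.data * 2.5, N=clpm_panel.N,
                              T=clpm_panel.T, truth=clpm_panel.truth,
                              generation_kind=clpm_panel.generation_kind,
                              seed=clpm_panel.seed)
        m2 = sample_moments(scaled)
        fit2 = fit_ml(m2, clpm_panel.N, "clpm", compute_se=False)
        s1 = fit_indices(fit1, m1, clpm_panel.N)[2]
        s2 = fit_indices(fit2, m2, clpm_panel.N)[2]
        assert s1 == pytest.approx(s2, rel=1e-3, abs=1e-6)


def test_fit_preconditions():
    truth = default_truth("clpm", 0.5, 0.2, T=4)
    m = implied_moments(truth, 4, "clpm")
    with pytest.raises(ValueError):
        fit_ml(m, 10, "clpm")          # N below parameter count
    # infeasible wave counts
    truth2 = default_truth("clpm", 0.5, 0.2, T=2)
    m2 = implied_moments(truth2, 2, "clpm")
    with pytest.raises(ValueError):
        fit_ml(m2, 1000, "ri_clpm")
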