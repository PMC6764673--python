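# Methods

## Model family

All three models share one state-space skeleton on the bivariate panel
(x_it, y_it), i = 1..N, t = 1..T, with the canonical stacking
(x_1, y_1, ..., x_T, y_T):

* **Temporal group means** mu_xt, mu_yt are saturated: one free mean per
  variable per occasion. The generator's default sets mu_t = t - 1 for both
  variables, so the marginal variances grow over time the way developmental
  panels often do.
* **Deviation process**: first-order bivariate autoregression on deviations,
  with time-invariant coefficient matrix B = [[beta_x, gamma_x], [gamma_y,
  beta_y]] and innovation covariance Omega. The t = 1 deviations are
  exogenous with a free 2x2 covariance block. Time-varying coefficients are
  out of scope by design: the moment builder accepts only time-invariant
  B, Omega, Psi (the "stability" assumption), which fixes the free-parameter
  counts at 2T + 10 / + 13 / + 16 for CLPM / RI-CLPM / STARTS.
* **Trait factors** (RI-CLPM, STARTS): zero-mean, time-invariant,
  uncorrelated with the initial deviations; covariance Phi enters every
  time-pair block of the implied covariance.
* **Measurement error** (STARTS): occasion-specific, covariance Psi on the
  same-time blocks only. This "temporal" contribution is exactly why the
  STARTS model is fragile: at later occasions the deviation variance grows
  while Psi stays fixed, so its relative share shrinks and its estimate is
  boundary-prone.

Minimum waves: 2 (CLPM), 3 (RI-CLPM), 4 (STARTS); fits below these raise,
and the study drivers mark such cells not-applicable rather than zero.

## Estimation

The fit minimizes the normal-theory discrepancy F_ML between the sample
moments (divisor-N covariance, so F_ML = 0 is exactly attainable) and the
implied moments. Because the mean structure is saturated, the ML solution
for the means is the sample mean for any covariance parameters; the
optimizer therefore profiles the means out and searches only the 10/13/16
covariance-side parameters. At the optimum the observed information is
block-diagonal between means and covariance parameters, so this loses
nothing: mean SEs are sqrt(diag(Sigma_hat)/N).

Numerical choices:

* **Unconstrained variances.** No log transform — negative variance
  estimates must be observable because they define improper solutions.
  When the implied covariance leaves the positive-definite cone, the
  objective returns a smooth penalty 1e6 (1 - lambda_min), pushing the
  search back without silent regularization.
* **Optimizer**: L-BFGS-B with an exact analytic gradient obtained by
  forward sensitivity of the block recursion (dV_t = B dV B' + dB V B' +
  B V dB' + dOmega, and the matching cross-block terms), memory maxcor=30,
  ftol 1e-13, projected-gradient tolerance 1e-6, at most 2000 iterations;
  on failure up to three deterministically jittered restarts before
  declaring nonconvergence (reported, never raised). The hot path runs as
  compiled numba kernels; a pure-numpy twin of the same computation is kept
  and the two are cross-validated against each other and against finite
  differences in the tests.
* **Starting values** are deterministic moment heuristics: means from the
  sample means; the smallest cross-time covariance as the trait variance
  (RI-CLPM, STARTS); a fixed tenth of the lag-0 variance as error variance
  (STARTS); pooled trait-corrected lag-1 least squares for B; residual and
  initial blocks from the implied recursion, with clamps so degenerate
  input still yields a finite start. When several kinds are fitted to the
  same data (`fit_models`), each richer model additionally starts from the
  best simpler solution with the added block at zero, which guarantees
  -2lnL(CLPM) >= -2lnL(RI-CLPM) >= -2lnL(STARTS) up to optimizer tolerance.
* **Standard errors**: observed information as the central-difference
  Jacobian of the exact gradient at the optimum, scaled by N/2; inverse
  diagonal entries that are not positive are reported NaN ("not testable"
  in Wald tests, distinct from non-significant).
* **Improper-solution classification**, in order: (1) any structural
  variance estimate (residual, initial, trait, error) below zero, or an
  estimated 2x2 block implying |correlation| > 1 (both reported as the
  out-of-range family under `negative_variance`); (2) reciprocal condition
  number of the approximate Hessian below 1e-10 (configurable) —
  `singular_hessian`; (3) optionally nonconvergence, off by default since
  the improper definition covers only the first two.
* **Wald tests** compare z = estimate/SE to the standard normal, two-sided;
  significance is strict (p < alpha), so at the exact boundary
  z = 1.959964 the test is not significant.
* **Fit indices**: chi2 = (N-1) F_ML, df = 2T + T(2T+1) - k;
  RMSEA = sqrt(max(chi2-df,0)/(df(N-1))); CFI against the independence
  baseline (free means/variances, zero covariances, closed-form
  F = sum ln S_jj - ln|S|); SRMR as the RMS of standardized covariance
  residuals over the upper triangle (mean residuals vanish under saturated
  means). Undefined (NaN) when df <= 0.

## The synthetic-data generator

`default_truth` encodes the study conditions: beta_x = beta_y = beta,
gamma_x = gamma_y = gamma, residual variances 0.2, initial deviation
variances 1 - psi^2, trait variances (1 - psi^2)/2, error variances psi^2
(STARTS generation only; forced 0 otherwise), every within-block
correlation 0.2, and means mu_t = t - 1. `simulate_panel` draws traits,
initial deviations, innovations and errors from the corresponding normal
blocks and propagates the recursion; identical (params, kind, N, T, seed)
give bit-identical panels.

What the generator does *not* emulate: missing data, non-normal residuals,
unequal time spacing, time-varying dynamics, person-varying coefficients,
more than two variables. Passing tests therefore say nothing about
robustness to those features of real panels.

## The Monte Carlo studies

**Improper-solution study.** Defaults follow the stated design: N in
{200, 600, 1000}, T in {4, 6, 8}, beta in {0.5, 0.7, 0.9}, gamma = 0.2,
psi^2 in {0.2, 0.5, 0.8} crossed only for STARTS generation, 200 trials
per condition (the acceptance script and tests use 50 and 25 with reduced
grids to keep desk-scale runtimes; the thresholds tested are those of the
full design). Every analysis model is fitted independently with its own
moment-based start. Marginal tables average per-condition proportions with
equal condition weights. Per-trial seeds derive from (master seed,
condition index, trial index) via `SeedSequence`, so runs are
bit-reproducible under any execution order, including parallel workers.

**Estimate-properties study.** Defaults: beta in {0.5, 0.7}, gamma in
{0, 0.1, 0.2}, psi^2 in {0.2, 0.4, 0.6}, 100 trials. A draw is retained
only when *all* requested analysis models converge with proper solutions
and testable cross-lagged SEs on that dataset, so the pairwise
significance-agreement tables compare fits on identical data; a condition
stops, flagged, after 50x the requested trials. Reported summaries: mean
SE of the cross-lagged estimates (gamma_x and gamma_y averaged),
four-category significance agreement per ordered model pair (one
comparison per cross-lagged parameter per trial), and AIC/BIC preference
proportions (lowest value wins).

## Known limitations

* The improper-solution frequency for a *correctly specified* STARTS model
  is optimizer-dependent in a way the misspecified cases are not. With
  exact-gradient optimization from moment-based starts, the global ML
  optimum at the default truth is proper in roughly half of the draws
  (aggregate ~47-50% improper over the full grid), with rates falling as N
  and T grow — the behavior expected of a consistent estimator whose truth
  lies in the interior. General-purpose SEM software run with default
  starting values can report substantially higher rates that *increase*
  with T, a pattern consistent with quasi-Newton searches terminating
  off-optimum (or with time-varying variance parameters in the analysis
  model, which this package deliberately excludes). The package reports what the ML estimator does, not what any
  particular optimizer's failure modes add on top.
* Fits are complete-data only; no FIML for missingness.
* Bayesian estimation and DIC are out of scope, as are multi-group and
  random-slope extensions.
* The singular-Hessian threshold (rcond < 1e-10) is a convention; in
  practice nearly all improper solutions at these designs are
  negative-variance cases, so conclusions are insensitive to it.
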