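# Methods

## Model

Each observation is an intersection-year at a given injury-severity level
(slight injury, or killed/seriously injured — KSI). The outcome is the
severity-specific crash rate, defined as crashes of that severity per
million vehicles of annual exposure; exposure is AADT × 365 and the rate
scale (10⁶) is a configuration option of `compute_crash_rate`. A
zero-crash intersection-year contributes a single observation with no
severity level; an intersection-year with any crashes contributes one
observation per severity category, censored (selection flag 0) when that
category saw no crashes. This expansion makes the selection structure
explicit: the model for severity level *k* is

- outcome:   y = x'β + μ          (crash rate of level k)
- selection: observed iff z'γ + υ > 0

with (μ, υ) bivariate normal, Var(μ) = σ², Var(υ) = 1, Corr = ρ. ρ ≠ 0 is
the selection bias: the unobservables that make a severity level occur
also move its rate.

Terminology note: the *inverse Mills ratio* is λ(a) = φ(a)/Φ(a); the
coefficient the second stage attaches to it estimates the *selection
coefficient* ρσ. The two are related but distinct objects, and the API
names them `inverse_mills` and `lambda_hat` (= `rho_hat * sigma_hat`)
respectively.

## Estimation

**First stage.** Probit by Newton–Raphson on the observed information,
starting from γ = 0, with step-halving; convergence when the gradient
max-norm < 1e-8 (`tol`), budget 100 iterations. The observed information
uses the identity d²logΦ(qc)/dc² = −δ(qc) with δ(a) = λ(a)(λ(a)+a) ∈
(0,1), which keeps the information positive semidefinite everywhere.
Separation — one-class outcomes, diverging iterates (|index| > 35), or a
final index that classifies every row with the correct sign — raises a
typed `SeparationError` instead of returning huge coefficients, because
downstream σ̂/ρ̂ recovery is meaningless under separation.

All normal-CDF arithmetic is in log space (`log_ndtr`). λ(a) is
exp(logφ − logΦ) for a ≥ −25 and the asymptotic expansion
−a + 1/(−a) − 2/(−a)³ + 10/(−a)⁵ below, avoiding cancellation between the
two large log terms deep in the lower tail.

**Second stage.** Least squares of y on [X, λ] over selected rows; then

- σ̂² = e'e/n₁ + mean(δᵢ)·β̂²_mills  (the δ term restores the variance the
  truncated residuals understate),
- ρ̂ = β̂_mills/σ̂, clamped to [−1, 1] with a flag when the finite-sample
  estimate overshoots (common at high |ρ| and small n; the flag, not an
  error, lets callers decide),
- covariance by the standard two-step asymptotic formula
  σ̂²(W'W)⁻¹[W'(I − ρ̂²Δ)W + ρ̂²(W'ΔZ)V_γ(Z'ΔW)](W'W)⁻¹ with Δ = diag(δᵢ),
  which accounts for both the induced heteroskedasticity and the
  estimated first-stage γ̂.

When nothing is censored (s ≡ 1) the Mills coefficient is unidentified and
the fit degenerates, by construction, to plain least squares with
ρ̂ = λ̂ = 0 — the uncensored limit of the model.

**FIML.** BFGS on the unconstrained parameterization (γ, β, atanh ρ,
log σ) with analytic gradients; gradient tolerance 1e-6; design columns
are scaled to unit SD internally (exactly undone afterwards) so that
traffic volumes in the tens of thousands and 0/1 indicators coexist
without ill-conditioning. The covariance is the inverse of a
central-difference Hessian of the analytic gradient, delta-method
transformed to the (ρ, σ) scale. Starting values default to the two-step
estimates. The Wald test of equation independence is (atanh ρ̂)²/
Var(atanh ρ̂) against χ²(1) — the transformed scale has better normal
approximation near the boundary. The FIML optimum always dominates the
two-step plug-in log likelihood; this inequality is asserted in tests.

The two-step estimator is the package default (it is cheap, transparent,
and the one practitioners report); FIML is `--method fiml`. In small
samples with a high true ρ the two-step ρ̂ can overshoot past 1 (it is
clamped and flagged); FIML, which enforces |ρ| < 1 by construction, is the
better-behaved choice there, and is what the acceptance script reports
for its small-sample pipeline run.

**Truncation effect.** effect = (multiplier) × (average Mills value over
selected rows); percent shift = 100(exp(effect) − 1). The multiplier is an
explicit argument: the pipeline default is ρ̂, with λ̂ = ρ̂σ̂ available
via configuration, since the two conventions coexist in the applied
literature. Percent shifts are computed at full precision; display
rounds half-even to two decimals.

**Bivariate probit.** The comparison model fits the two severity
indicators jointly; each row contributes an orthant probability
Φ₂(q₁x₁'β₁, q₂x₂'β₂, q₁q₂ρ) with qⱼ = 2sⱼ − 1. Φ₂ is computed by 64-node
Gauss–Legendre quadrature of the trigonometric Drezner–Wesolowsky
correlation integral
Φ₂(a,b,r) = Φ(a)Φ(b) + (1/2π)∫₀^{asin r} exp(−(a² − 2ab sin t + b²)/
(2cos²t)) dt, accurate to ~1e-14 at moderate |r| and better than 1e-10 up
to |r| = 0.99; tests cross-check it against an independent CDF
implementation and the closed form at the origin. Optimization is BFGS on
(β₁, β₂, atanh ρ) from univariate-probit starts; a correlation driven to
the boundary by perfectly concordant outcomes is clamped at ±0.999 and
flagged.

**Goodness of fit.** MAD = mean|Y − Ŷ|, RMSE = √(mean(Y − Ŷ)²). Ŷ is the
conditional-on-selection mean x'β̂ + β̂_mills λ(z'γ̂), scored on selected
rows — the object the estimator actually fits. Whether to score all rows
or selected rows is config-exposed; reported MAD/RMSE therefore measure
in-sample conditional fit, not population prediction.

## Synthetic data

The generator reproduces the model's assumptions exactly: independent
covariate draws from configurable marginals (normal, lognormal —
parameterized by arithmetic mean/SD —, Bernoulli, uniform), errors built
as υ ~ N(0,1), μ = σ(ρυ + √(1−ρ²)w) so the target covariance is exact by
construction, and selection/outcome per the latent rule. A single global
seed drives a spawned per-stage seed sequence, so the covariate draw and
the error draw are independently reproducible.

The default "hk-like" scenario mirrors the marginal moments of a dense
urban signalized-intersection network: AADT lognormal with mean 35,934
and SD 23,219 vehicles/day, cycle time N(98.3, 18.3²) s, speed limit
N(50, 0.85²) km/h, tram stops at 6% of sites, the Kowloon-district flag
at 58%, and so on. Selection coefficients follow the sign pattern such
networks show (volume, tight turning radii, tram stops and dense district
raise the chance a severity level is observed; higher speed limits lower
the slight-injury chance), with the intercept set so ≈75% of observations
are selected — matching the roughly three-quarters non-zero-crash share
of such samples — and outcome coefficients putting the mean crash rate
near 0.6 per million vehicles. These magnitudes are package defaults for
a realistic scenario, not estimates of any particular network.

What the generator does *not* emulate: dependence between covariates
(only marginals are specified; independence is a simplification), spatial
or temporal correlation between intersections or years, and count-data
structure (the outcome is the continuous rate the model uses, not a
Poisson/NB count). Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions — not
robustness to real-data violations of them.

## Problem sizes and tolerances

Recovery tests use n = 20,000 (point recovery: two-step ρ within ±0.1, σ
within ±0.05; FIML ±0.05/±0.03), n = 5,000 for replicate averages (mean
ρ̂ within 0.05 over 20 replicates), and 200 replicates of n = 2,000 for
the Wald test's type-I error (5% ± 3 points). Likelihood identities are
checked to 1e-10 relative error; quadrature and closed-form oracles to
1e-10 absolute. Grid-search oracles (probit 200×200, FIML 13⁴) assert
agreement to grid resolution. These sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping the full suite around
ten seconds.

## Known limitations

- The two-step covariance assumes homoskedastic μ; no cluster-robust
  option (intersections appear in two years and could be clustered).
- Identification leans on functional form when X and Z overlap heavily;
  the generator's default includes genuine exclusion restrictions, real
  specifications may not, and two-step finite-sample bias grows
  accordingly.
- Only the binary slight/KSI severity split is supported; no ordered or
  multinomial severities, and no count-outcome selection models.
- Observation expansion for multi-crash intersection-years follows one
  defensible bookkeeping rule (one row per severity category once any
  crash occurs); alternative conventions exist and change sample counts.
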