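# Methods

## Model

For subject `i` let `t_i > 0` be the observed time, `δ_i ∈ {0,1}` the event
indicator (1 = event, 0 = right-censored) and `x_i` the covariate vector
with an explicit intercept slot.  The AFT model in the log-location-scale
family is

    y_i = log t_i = β' x_i + b Z_i,

with scale `b > 0` and standardized error `Z`.  Three members are built in:

| error distribution | log f0(z)              | log S0(z)          | survival time |
|--------------------|------------------------|--------------------|---------------|
| extreme value      | `z − e^z`              | `−e^z`             | Weibull       |
| normal             | `−z²/2 − log√(2π)`     | `log Φ(−z)`        | log-normal    |
| logistic           | `z − 2 log(1 + e^z)`   | `−log(1 + e^z)`    | log-logistic  |

The registry is extensible; each entry carries the first and second
derivatives of `log f0` and `log S0` in closed form, all verified against
central finite differences in the test suite.  The CDF convention is
`F0 = 1 − S0` throughout; quantile functions invert `F0`.

Numerical choices at the distribution level: the normal log-survivor and
hazard are evaluated through `scipy.special.log_ndtr` (scaled-erfc /
Mills-ratio form) because the naive `log(1 − Φ(z))` underflows near
`z ≈ 8`, which destroys the observed information exactly in the
heavy-censoring settings the package targets; logistic expressions run
through `logaddexp`/`expit`.

## Likelihood, score, information

With `z_i = (y_i − β'x_i)/b` and `m = Σ δ_i`:

    ℓ(β, b) = −m log b + Σ_i [ δ_i log f0(z_i) + (1 − δ_i) log S0(z_i) ]

Per-subject derivatives `B_i` (first) and `A_i` (second) of the
`δ`-weighted mixture give the analytic score

    U_r = −(1/b) Σ_i B_i x_ir,      U_b = −m/b − (1/b) Σ_i B_i z_i,

and the observed information

    I(β,b) = (1/b²) [ −Σ A_i x_i x_i'            −Σ (A_i z_i + B_i) x_i
                      −Σ (A_i z_i + B_i) x_i'    −(m + Σ (A_i z_i² + 2 B_i z_i)) ].

Note the leading term of `U_b` is `−m/b`, the derivative of `−m log b`;
some presentations of these equations misprint the numerator.

## Fitting

ML fits optimize over `(β, log b)` — unconstrained and better conditioned
than `b` — by BFGS with the analytic score (chain rule on the last
component).  Starting values: OLS of `y` on `X` over all rows (censored
included), scale from the residual SD floored at 1e-3.  Convergence:
gradient max-norm ≤ 1e-6, iteration cap 500; an exit with gradient norm
≤ 1e-5 still counts as converged.  The covariance is the inverse observed
information at the optimum on the `(β, b)` scale (the information above is
already parameterized in `(β, b)`, so no Jacobian correction is needed).
If the information is singular at the optimum the point estimate is kept
and `cov_status="singular"` flags the missing SEs.  A fixed offset can be
added to the location (`u_i = offset_i + β'x_i`), which is how the
intercept/scale correction reuses the fitter.

## Firth penalization

The penalized objective is `ℓ* = ℓ + ½ log |I(β,b)|`.  The fit maximizes
`ℓ*` directly (again BFGS over `(β, log b)`) rather than solving the
modified score equations: the latter needs `∂I/∂θ`, i.e. third derivatives
of `log f0`/`log S0`.  Design choices:

* `log |I|` is computed via Cholesky; outside the positive-definite region
  the objective returns a large negative value so line searches retreat
  into the valid region without crashing.
* The optimizer's gradient is the analytic score of `ℓ` plus a central
  finite-difference gradient of the scalar penalty (step
  `1e-6·max(1,|θ_k|)`).  The trace identity
  `∂/∂θ_k ½log|I| = ½ tr[I⁻¹ ∂I/∂θ_k]` is implemented as an independent
  route and cross-checked in the tests, not used in the hot path.
* Starting point: the MLE when it converges with max |θ| < 50, otherwise
  the OLS start — separated datasets still start sensibly.
* Standard errors are the inverse negative Hessian of the *penalized*
  objective at the optimum (central differences, step `1e-4·max(1,|θ|)`),
  i.e. the curvature of the function actually optimized.  Whether to use
  penalized or unpenalized curvature is genuinely open; the penalized
  choice is the literal reading of "standard errors from the approximated
  Hessian" and is the documented interpretation here.

The penalty is equivariant under covariate rescaling (it shifts by an
additive constant, `+log c` per column scaled by `c`), so penalized
estimates transform exactly like ML estimates.

## Intercept/scale correction

Firth shrinkage of `(β_0, b)` biases predicted survival.  The correction
computes `η_i = Σ_{r≥1} β_{F,r} x_{ir}`, fits the two-parameter model
`Y = β_0 + η + bZ` by ML with `η` as a fixed offset, and splices the
resulting `(β_0, b)` (and their 2×2 ML covariance) into the Firth result.
Slopes and slope SEs are carried over bit-for-bit.  The corrected
intercept/scale SEs ignore slope-estimation uncertainty; joint propagation
is out of scope.  With no covariates the correction reduces exactly to the
null-model MLE.

## Separation diagnostic

For a 0/1 covariate the diagnostic builds the 2×2 table of covariate level
by event status and compares the two groups' survival with a log-rank test
(the test behind the "significantly different median survival" rule is a
design choice; log-rank is the standard two-group censored comparison).
Classification: *separation* if any cell is 0 or p < 0.01; *near* if any
cell ≤ 5 or 0.01 ≤ p < 0.05; otherwise *none*.  Detection of separation
along linear combinations of covariates is deliberately not attempted.

## Synthetic data and the Monte Carlo runner

The generator emulates a two-covariate design: `X_c ~ N(0,1)`,
`X_b ~ Bernoulli(π)` (default `π = 0.5`, the neutral choice when no value
is dictated), survival times `T = exp(β_0 + β_b X_b + β_c X_c + b Z)` and
censoring times `C = exp(λ + b Z')` from the same family, observed
`t = min(T, C)`, `δ = 1{T ≤ C}`.  Default true values are
`β = (3, 0.7, 1.2)` with `b = 0.67` (binary coefficient 0.7, continuous
1.2); the separation-prone design strengthens the binary covariate to
`β_b = 1.9` with `β_c = 0.5`.  `λ` is calibrated once per scenario by
bisection on a 200 000-draw auxiliary sample (own seed stream, tolerance
±0.005 on the censoring proportion); the censoring fraction is monotone in
`λ`, so bisection is exact up to Monte Carlo granularity.

The runner spawns one RNG substream per replicate from the scenario seed
(bit-reproducible, order-independent), optionally regenerates each
replicate until the separation diagnostic matches a requested status
(screening defines a clean conditional distribution; cap 10 000 attempts),
fits ML, Firth and corrected Firth, and aggregates over *valid* replicates:
a fit is invalid when it fails to converge, any |estimate| exceeds
`max_abs_coef` (default 50, configurable — set it to infinity to keep
diverged MLEs in the average as some reference software effectively does),
or any SE is non-finite.  Reported metrics per parameter: mean estimate,
bias (mean − truth), MSE (mean squared deviation from truth), mean
analytic SE, simulation SE (SD of estimates, ddof 1), and mean Wald 95%
CI width (`2·1.96·SE` averaged over replicates).

What the generator does *not* emulate: covariate-dependent censoring,
model misspecification (the fitted family always matches the generating
family), correlated or more than two covariates, ties from coarse time
recording.  Passing simulation tests therefore demonstrates estimator
behaviour under a correctly specified model, not robustness.

Log-times are settled on a fixed point of `log(exp(·))` and CSV parsing
uses correctly-rounded floats, so a dataset written to text and re-read
reproduces the identical fit bit-for-bit.

## Problem sizes

The bundled studies use the small-sample grid the method is designed for
(n = 30–100, censoring 10–80%, 1000 replicates; 500 for the prediction
study), which keeps a full run of the test suite and the reproduction
script to a few minutes on one CPU.  Large-sample checks (n = 10⁴) verify
consistency and ML/Firth asymptotic agreement for all three distributions.

## Known limitations

* Wald intervals only; the penalized SEs can understate variability in
  extreme censoring, and profile-penalized-likelihood intervals are not
  implemented.
* Corrected-fit SEs for `(β_0, b)` condition on the slopes.
* The separation diagnostic covers a single binary covariate at a time.
* No left truncation, interval censoring, time-varying covariates or
  frailty.
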