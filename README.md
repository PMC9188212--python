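# firthaft

Firth-penalized accelerated failure time (AFT) models for right-censored
survival data with small samples, heavy censoring, or separation.

## The problem

Parametric AFT models in the log-location-scale family write the log
survival time as

```
y_i = log t_i = β'x_i + b Z_i,        z_i = (y_i − β'x_i) / b,
```

where the standard error distribution of `Z` is extreme value (Gumbel),
normal, or logistic — making `T` Weibull, log-normal, or log-logistic.  The
censored-data log-likelihood, with `δ_i = 1` for events and `m = Σδ_i`, is

```
ℓ(β, b) = −m log b + Σ_i [ δ_i log f0(z_i) + (1 − δ_i) log S0(z_i) ].
```

When the sample is small, censoring heavy, or a binary covariate aligns
(nearly) perfectly with event status — *separation*, or monotone
likelihood — the MLE of one or more coefficients drifts to infinity and
Wald intervals become useless.  The remedy implemented here penalizes the
likelihood with the log of the Jeffreys invariant prior,

```
ℓ*(β, b) = ℓ(β, b) + ½ log |I(β, b)|,
```

where `I` is the (p+2)×(p+2) observed information (scale included).  The
penalty removes the O(1/n) bias term, guarantees finite estimates under
separation, and vanishes asymptotically.  Because the penalty also shrinks
the intercept and scale — which biases predicted survival probabilities —
a post-hoc correction re-estimates `(β_0, b)` by plain ML with the
penalized slope linear predictor held fixed as an offset.  Survival
prediction then uses `S(t|x) = S0((log t − β'x)/b)`.

The package is aimed at biostatisticians fitting parametric survival
models to small or rare-event cohorts, and contains: the three standard
distributions with all derivatives needed for the score and information;
ML and Firth fitting (BFGS on `(β, log b)` with analytic scores); the
intercept/scale correction; survival prediction; a separation diagnostic
(2×2 event-by-covariate table plus a log-rank comparison); and the full
Monte Carlo machinery (censoring-parameter calibration, scenario runner,
bias/MSE/CI-width summaries) used to evaluate the estimators.

## Worked example

```python
import numpy as np
import firthaft as fa

scenario = fa.Scenario(dist="weibull", n=30, true_beta=(3.0, 0.7, 1.2),
                       true_b=0.67, target_censoring=0.4, n_reps=1, seed=8)
lam = fa.calibrate_lambda(scenario)                  # censoring constant
data, cens = fa.generate_dataset(scenario, lam, np.random.default_rng(8))

mle = fa.fit_mle(data, "weibull")
firth = fa.fit_firth(data, "weibull")
corrected = fa.correct_intercept_scale(data, "weibull", firth)
print(corrected.to_frame().round(3))

x = np.array([1.0, 1.0, 0.0])                        # x_b = 1, x_c = 0
print(fa.predict_survival(corrected, "weibull", x, 20.0))
print(fa.classify_separation(data, "x_b").status)
```

prints

```
             estimate     se  ci_low  ci_high
(Intercept)     2.614  0.095   2.428    2.799
x_b             0.765  0.171   0.430    1.101
x_c             1.040  0.119   0.807    1.273
scale           0.410  0.070   0.272    0.548
0.6745937284151646
near
```

The coefficient table shows the corrected Firth estimates with Wald 95%
intervals: at n = 30 with ~40% censoring the penalized fit pulls both
coefficients toward zero relative to the MLE (which here gives 0.757 and
1.090 with wider intervals) while the corrected intercept/scale keep
survival predictions calibrated — a subject with the binary covariate at 1
and the continuous covariate at its mean has an estimated 67% chance of
surviving past t = 20.  The `near` status warns that one cell of the
event-by-covariate table is small (≤ 5), i.e. the data are close to
separation and plain ML should be treated with suspicion.

A console script exposes the same functionality:

```
firthaft fit --input data.csv --covariates x_b,x_c --dist weibull --method firth
firthaft diagnose --input data.csv --covariates x_b,x_c --binary x_b
firthaft simulate --config scenario.yaml --out summary.csv
```

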