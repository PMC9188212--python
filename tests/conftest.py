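import numpy as np
import pytest

import firthaft as fa


def simulate_data(dist="weibull", n=60, beta=(3.0, 0.7, 1.2), b=0.67,
                  target_censoring=0.2, seed=0):
    """One dataset from the standard two-covariate design."""
    sc = fa.Scenario(dist=dist, n=n, true_beta=tuple(beta), true_b=b,
                     target_censoring=target_censoring, n_reps=1, seed=seed)
    lam = fa.calibrate_lambda(sc) if target_censoring > 0 else \
        fa.simulation.no_censoring_lambda(sc)
    data, _ = fa.generate_dataset(sc, lam, np.random.default_rng(seed + 1))
    return data


def separated_dataset(n=30, seed=7, dist="weibull"):
    """Binary covariate perfectly aligned with event status (zero cell)."""
    rng = np.random.default_rng(seed)
    half = n // 2
    delta = np.array([1.0] * half + [0.0] * (n - half))
    xb = 1.0 - delta  # censored subjects carry x_b = 1 -> monotone likelihood
    xc = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), xb, xc])
    d = fa.get_distribution(dist)
    z = d.quantile(np.clip(rng.random(n), 1e-12, 1 - 1e-12))
    y = X @ np.array([3.0, 1.2, 0.7]) + 0.67 * z
    return fa.SurvivalDataset(y=y, delta=delta, X=X, covariate_names=("x_b", "x_c"))


@pytest.fixture
def weibull_data():
    return simulate_data(seed=3)


@pytest.fixture
def uncensored_normal_data():
    rng = np.random.default_rng(11)
    n = 60
    X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.standard_normal(n)])
    y = X @ np.array([1.0, 0.5, -0.3]) + 0.8 * rng.standard_normal(n)
    return fa.SurvivalDataset(y=y, delta=np.ones(n), X=X, covariate_names=("a", "b"))
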