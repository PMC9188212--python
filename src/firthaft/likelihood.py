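"""Likelihood, score, observed information and ML fitting for AFT models.

The model: for subject ``i`` with log-time ``y_i``, event indicator
``delta_i`` (1 = event, 0 = right-censored) and covariate row ``x_i``
(intercept included),

    y_i = beta' x_i + b Z_i,        z_i = (y_i - beta' x_i) / b,

with ``Z`` from a standard location-scale distribution.  Writing
``m = sum(delta)``, the censored-data log-likelihood is

    l(beta, b) = -m log b
                 + sum_i [ delta_i log f0(z_i) + (1 - delta_i) log S0(z_i) ].

The score and the (p+2)x(p+2) observed information are assembled from the
per-subject quantities

    B_i = delta_i dlogf0(z_i) + (1 - delta_i) dlogS0(z_i),
    A_i = delta_i d2logf0(z_i) + (1 - delta_i) d2logS0(z_i),

as

    U_r = -(1/b) sum_i B_i x_ir,
    U_b = -m/b - (1/b) sum_i B_i z_i,
    I   = (1/b^2) [ [-sum A_i x_i x_i',        -sum (A_i z_i + B_i) x_i      ],
                    [-sum (A_i z_i + B_i) x_i', -(m + sum (A_i z_i^2 + 2 B_i z_i))] ].

Fitting maximizes the log-likelihood over ``(beta, log b)`` (unconstrained,
better conditioned than ``b`` itself) with BFGS and the analytic score; the
reported covariance is the inverse observed information on the ``(beta, b)``
scale.  An optional fixed offset enters the location as
``u_i = offset_i + beta' x_i`` (used by the intercept/scale correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .distributions import StandardDistribution, get_distribution

__all__ = [
    "SurvivalDataset",
    "ParamVector",
    "FitResult",
    "loglik",
    "score",
    "observed_information",
    "fit_mle",
]

#: max |gradient| at which a non-"success" optimizer exit still counts as converged
_GRAD_ACCEPT = 1e-5
_BIG = 1e10


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored sample: log-times, event indicators, design matrix.

    ``y`` holds log survival/censoring times, ``delta`` the 0/1 event
    indicators (1 = event), and ``X`` the n x (p+1) design matrix whose first
    column is all ones.  ``covariate_names`` labels the non-intercept columns.
    """

    y: np.ndarray
    delta: np.ndarray
    X: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(y)):
            raise ValueError("log-times must be finite (all times > 0)")
        if not np.all(np.isin(delta, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        if X.shape[0] != y.size or delta.size != y.size:
            raise ValueError("y, delta and X must have matching lengths")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first column of the design matrix must be ones")
        names = tuple(str(c) for c in self.covariate_names)
        if names and len(names) != X.shape[1] - 1:
            raise ValueError("covariate_names must label the non-intercept columns")
        if not names:
            names = tuple(f"x{j}" for j in range(1, X.shape[1]))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        """Number of covariates, excluding the intercept."""
        return self.X.shape[1] - 1

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    @property
    def term_names(self) -> tuple[str, ...]:
        return ("(Intercept)",) + self.covariate_names + ("scale",)


@dataclass(frozen=True)
class ParamVector:
    """AFT parameters: regression coefficients (intercept first) and scale."""

    beta: np.ndarray
    b: float

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        b = float(self.b)
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        if not (math.isfinite(b) and b > 0.0):
            raise ValueError("scale b must be finite and > 0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "b", b)

    @property
    def theta(self) -> np.ndarray:
        """Full parameter vector (beta_0, ..., beta_p, b)."""
        return np.concatenate([self.beta, [self.b]])


@dataclass
class FitResult:
    """Outcome of an AFT fit (ML, Firth, or Firth + intercept/scale fix)."""

    params: ParamVector
    se: np.ndarray
    cov: np.ndarray
    objective: float
    converged: bool
    n_iter: int
    method: str
    gradient_norm: float
    names: tuple[str, ...] = ()
    cov_status: str = "ok"  # "ok" | "singular"

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE and Wald 95% CI per term."""
        est = self.params.theta
        lo = est - 1.96 * self.se
        hi = est + 1.96 * self.se
        names = self.names if self.names else tuple(f"theta{k}" for k in range(est.size))
        return pd.DataFrame(
            {"estimate": est, "se": self.se, "ci_low": lo, "ci_high": hi},
            index=list(names),
        )


def _zvals(data: SurvivalDataset, params: ParamVector, offset) -> np.ndarray:
    u = data.X @ params.beta
    if offset is not None:
        u = u + np.asarray(offset, dtype=float)
    return (data.y - u) / params.b


def loglik(data: SurvivalDataset, dist, params: ParamVector, offset=None) -> float:
    """Censored-data log-likelihood at ``params``."""
    d = get_distribution(dist)
    z = _zvals(data, params, offset)
    delta = data.delta
    m = data.n_events
    terms = delta * d.log_f0(z) + (1.0 - delta) * d.log_S0(z)
    return float(-m * math.log(params.b) + terms.sum())


def _B(d: StandardDistribution, z, delta):
    return delta * d.logf0_d1(z) + (1.0 - delta) * d.logS0_d1(z)


def _A(d: StandardDistribution, z, delta):
    return delta * d.logf0_d2(z) + (1.0 - delta) * d.logS0_d2(z)


def score(data: SurvivalDataset, dist, params: ParamVector, offset=None) -> np.ndarray:
    """Analytic score (gradient of :func:`loglik`) in the order (beta, b)."""
    d = get_distribution(dist)
    z = _zvals(data, params, offset)
    B = _B(d, z, data.delta)
    b = params.b
    u_beta = -(data.X.T @ B) / b
    u_b = -data.n_events / b - float(B @ z) / b
    return np.concatenate([u_beta, [u_b]])


def observed_information(
    data: SurvivalDataset, dist, params: ParamVector, offset=None
) -> np.ndarray:
    """Observed information (negative Hessian of :func:`loglik`), (p+2)x(p+2)."""
    d = get_distribution(dist)
    z = _zvals(data, params, offset)
    delta = data.delta
    A = _A(d, z, delta)
    B = _B(d, z, delta)
    X = data.X
    b2 = params.b ** 2
    block_bb = -(X.T * A) @ X
    cross = -(X.T @ (A * z + B))
    corner = -(data.n_events + float(A @ (z * z)) + 2.0 * float(B @ z))
    k = X.shape[1] + 1
    info = np.empty((k, k))
    info[:-1, :-1] = block_bb
    info[:-1, -1] = cross
    info[-1, :-1] = cross
    info[-1, -1] = corner
    return info / b2


def _check_full_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag.max() if diag.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")


def _ols_start(data: SurvivalDataset, offset) -> ParamVector:
    """OLS of (possibly offset-adjusted) log-time on X; residual SD as scale."""
    y = data.y if offset is None else data.y - np.asarray(offset, dtype=float)
    beta, *_ = np.linalg.lstsq(data.X, y, rcond=None)
    resid = y - data.X @ beta
    b0 = max(float(np.std(resid)), 1e-3)
    return ParamVector(beta, b0)


def _pack(params: ParamVector) -> np.ndarray:
    return np.concatenate([params.beta, [math.log(params.b)]])


def _unpack(x: np.ndarray) -> ParamVector:
    return ParamVector(x[:-1], math.exp(float(x[-1])))


def _covariance_from_information(info: np.ndarray):
    """Invert an information matrix via Cholesky; None when not PD."""
    try:
        c, low = linalg.cho_factor(info)
    except linalg.LinAlgError:
        return None
    return linalg.cho_solve((c, low), np.eye(info.shape[0]))


def fit_mle(
    data: SurvivalDataset,
    dist,
    init: ParamVector | None = None,
    offset=None,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> FitResult:
    """Maximum likelihood fit of the AFT model.

    Optimizes over ``(beta, log b)`` with BFGS and the analytic score; the
    covariance is the inverse observed information at the optimum on the
    ``(beta, b)`` scale.  ``converged`` is False when the gradient norm is
    still above tolerance at the iteration cap; a singular information matrix
    at the optimum leaves the point estimate but flags ``cov_status``.
    """
    d = get_distribution(dist)
    if data.n_events == 0:
        raise ValueError("cannot fit: no events in the data (all subjects censored)")
    if data.n < data.X.shape[1] + 1:
        raise ValueError(f"need at least p+2 = {data.X.shape[1] + 1} subjects")
    _check_full_rank(data.X, ("(Intercept)",) + data.covariate_names)

    x0 = _pack(init if init is not None else _ols_start(data, offset))

    def negobj(x):
        if abs(x[-1]) > 200.0:  # exp over/underflow guard
            return _BIG
        with np.errstate(over="ignore", invalid="ignore"):
            val = loglik(data, d, _unpack(x), offset)
        return -val if math.isfinite(val) else _BIG

    def neggrad(x):
        if abs(x[-1]) > 200.0:
            return np.zeros_like(x)
        pv = _unpack(x)
        with np.errstate(over="ignore", invalid="ignore"):
            s = score(data, d, pv, offset)
        s[-1] *= pv.b  # chain rule for the log-b parameterization
        if not np.all(np.isfinite(s)):
            return np.zeros_like(x)
        return -s

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            negobj, x0, jac=neggrad, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )

    params = _unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm <= _GRAD_ACCEPT

    k = data.X.shape[1] + 1
    info = observed_information(data, d, params, offset)
    cov = _covariance_from_information(info)
    if cov is None:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)
        status = "singular"
    else:
        diag = np.diag(cov)
        se = np.sqrt(np.clip(diag, 0.0, None))
        status = "ok"

    return FitResult(
        params=params,
        se=se,
        cov=cov,
        objective=float(-res.fun),
        converged=converged,
        n_iter=int(res.nit),
        method="mle",
        gradient_norm=grad_norm,
        names=data.term_names,
        cov_status=status,
    )
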