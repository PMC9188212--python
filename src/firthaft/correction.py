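"""Post-hoc intercept and scale correction for Firth-penalized AFT fits.

The Jeffreys-prior penalty shrinks all parameters, including the intercept
and the scale; left uncorrected this biases predicted survival
probabilities.  The remedy keeps the penalized slopes but re-estimates
``(beta_0, b)`` by plain maximum likelihood with the slope linear predictor
held fixed:

1. obtain the Firth estimates (beta_F, b_F);
2. form the linear predictor eta_i = sum_{r>=1} beta_{F,r} x_{ir},
   omitting the intercept;
3. fit the two-parameter model  Y = beta_0 + eta + b Z  by ML, with eta
   entering the location as a fixed offset (coefficient pinned at one);
4. splice the offset-model (beta_0, b) into the Firth estimate.

Slope estimates and slope standard errors are carried over unchanged from
the Firth fit; the corrected intercept/scale SEs come from the offset
model's own 2x2 observed information, which ignores slope-estimation
uncertainty (a documented limitation).
"""

from __future__ import annotations

import numpy as np

from .distributions import get_distribution
from .likelihood import FitResult, ParamVector, SurvivalDataset, fit_mle

__all__ = ["CorrectionError", "correct_intercept_scale"]


class CorrectionError(RuntimeError):
    """Offset-model refit failed; carries the unmodified Firth fit."""

    def __init__(self, message: str, firth_fit: FitResult):
        super().__init__(message)
        self.firth_fit = firth_fit
        self.status = "correction_failed"


def correct_intercept_scale(
    data: SurvivalDataset, dist, firth_fit: FitResult
) -> FitResult:
    """Re-estimate intercept and scale by ML with Firth slopes as an offset.

    Returns a :class:`FitResult` with method ``"firth_corrected"`` whose
    slope entries (estimates and SEs) are identical to ``firth_fit`` and
    whose intercept/scale are the offset-model MLEs.
    """
    d = get_distribution(dist)
    if firth_fit.method != "firth":
        raise ValueError("correction expects a Firth fit (method='firth')")
    if not firth_fit.converged:
        raise ValueError("correction expects a converged Firth fit")

    eta = data.X[:, 1:] @ firth_fit.params.beta[1:]
    null_data = SurvivalDataset(
        y=data.y, delta=data.delta, X=np.ones((data.n, 1)), covariate_names=()
    )
    try:
        sub = fit_mle(null_data, d, offset=eta)
    except Exception as exc:  # structural failure of the 2-parameter problem
        raise CorrectionError(
            f"offset-model refit failed: {exc}", firth_fit
        ) from exc
    if not sub.converged:
        raise CorrectionError("offset-model refit did not converge", firth_fit)

    beta = firth_fit.params.beta.copy()
    beta[0] = sub.params.beta[0]
    params = ParamVector(beta, sub.params.b)

    se = firth_fit.se.copy()
    se[0] = sub.se[0]
    se[-1] = sub.se[-1]
    cov = firth_fit.cov.copy()
    # splice the offset model's 2x2 covariance for (beta_0, b)
    cov[0, 0] = sub.cov[0, 0]
    cov[-1, -1] = sub.cov[-1, -1]
    cov[0, -1] = cov[-1, 0] = sub.cov[0, -1]

    return FitResult(
        params=params,
        se=se,
        cov=cov,
        objective=sub.objective,  # offset-model log-likelihood at (beta_0, b)
        converged=True,
        n_iter=sub.n_iter,
        method="firth_corrected",
        gradient_norm=sub.gradient_norm,
        names=firth_fit.names,
        cov_status="ok" if (sub.cov_status == "ok" and firth_fit.cov_status == "ok") else "singular",
    )
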