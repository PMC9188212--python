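"""Survival-probability and survival-time-quantile prediction.

For a fitted AFT model the survivor function at covariate vector ``x``
(intercept slot included) is

    S(t | x) = S0( (log t - beta' x) / b ),

and the time at which survival drops to ``1 - q`` is

    t_q = exp( beta' x + b * z_q ),    F0(z_q) = q,

so ``predict_survival(predict_time_quantile(q)) == 1 - q`` exactly.
"""

from __future__ import annotations

import numpy as np

from .distributions import get_distribution
from .likelihood import FitResult, ParamVector

__all__ = ["predict_survival", "predict_time_quantile"]


def _params(fit) -> ParamVector:
    if isinstance(fit, FitResult):
        return fit.params
    if isinstance(fit, ParamVector):
        return fit
    raise TypeError("fit must be a FitResult or ParamVector")


def predict_survival(fit, dist, x, t):
    """Predicted survival probability S(t | x); vectorized over ``t``."""
    d = get_distribution(dist)
    pv = _params(fit)
    x = np.asarray(x, dtype=float)
    if x.shape != pv.beta.shape:
        raise ValueError("covariate vector length must match beta (intercept slot included)")
    t_arr = np.asarray(t, dtype=float)
    if not np.all(t_arr > 0.0):
        raise ValueError("t must be > 0")
    z = (np.log(t_arr) - float(pv.beta @ x)) / pv.b
    out = np.exp(d.log_S0(z))
    return float(out) if np.ndim(t) == 0 else out


def predict_time_quantile(fit, dist, x, q):
    """Time t with S(t | x) = 1 - q; vectorized over ``q``."""
    d = get_distribution(dist)
    pv = _params(fit)
    x = np.asarray(x, dtype=float)
    if x.shape != pv.beta.shape:
        raise ValueError("covariate vector length must match beta (intercept slot included)")
    q_arr = np.asarray(q, dtype=float)
    if not np.all((q_arr > 0.0) & (q_arr < 1.0)):
        raise ValueError("q must lie strictly inside (0, 1)")
    out = np.exp(float(pv.beta @ x) + pv.b * d.quantile(q_arr))
    return float(out) if np.ndim(q) == 0 else out
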