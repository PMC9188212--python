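"""Central finite-difference helpers for scalar objectives."""

from __future__ import annotations

import numpy as np


def _steps(x: np.ndarray, rel_step: float) -> np.ndarray:
    return rel_step * np.maximum(1.0, np.abs(x))


def approx_gradient(f, x, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function.

    Non-finite one-sided values fall back to a one-sided difference against
    f(x); if both sides are unusable the component is set to 0 (the caller is
    expected to be near the interior of the valid region).
    """
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.zeros_like(x)
    f0 = None
    for k in range(x.size):
        e = np.zeros_like(x)
        e[k] = h[k]
        fp, fm = f(x + e), f(x - e)
        if np.isfinite(fp) and np.isfinite(fm):
            g[k] = (fp - fm) / (2.0 * h[k])
        else:
            if f0 is None:
                f0 = f(x)
            if np.isfinite(fp) and np.isfinite(f0):
                g[k] = (fp - f0) / h[k]
            elif np.isfinite(fm) and np.isfinite(f0):
                g[k] = (f0 - fm) / h[k]
    return g


def approx_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function (symmetric by build)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = _steps(x, rel_step)
    H = np.empty((n, n))
    f0 = f(x)
    for k in range(n):
        ek = np.zeros(n)
        ek[k] = h[k]
        H[k, k] = (f(x + ek) - 2.0 * f0 + f(x - ek)) / h[k] ** 2
        for l in range(k + 1, n):
            el = np.zeros(n)
            el[l] = h[l]
            H[k, l] = H[l, k] = (
                f(x + ek + el) - f(x + ek - el) - f(x - ek + el) + f(x - ek - el)
            ) / (4.0 * h[k] * h[l])
    return H
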