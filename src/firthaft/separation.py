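"""Separation diagnostics for censored data with a binary covariate.

Separation (monotone likelihood) arises when a binary covariate aligns
perfectly -- or nearly so -- with event status, driving an ML coefficient to
infinity.  The diagnostic builds the 2x2 contingency table of covariate
level by event status and compares the two groups' survival with a log-rank
test (the standard two-group censored-data comparison, used here for the
"median survival times significantly different" rule):

* ``separation``: any zero cell, or log-rank p < 0.01;
* ``near``: otherwise, any cell <= 5, or 0.01 <= p < 0.05;
* ``none``: everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines.statistics import logrank_test

from .likelihood import SurvivalDataset

__all__ = ["SeparationReport", "classify_separation"]


@dataclass(frozen=True)
class SeparationReport:
    """2x2 table (covariate 0/1 rows x censored/event columns) and status."""

    table: np.ndarray  # rows: covariate level 0, 1; cols: delta = 0, 1
    min_cell: int
    group_test_p: float  # log-rank p-value; NaN if a group is empty
    status: str  # "none" | "near" | "separation"


def _resolve_column(data: SurvivalDataset, binary_col) -> int:
    if isinstance(binary_col, str):
        try:
            return data.covariate_names.index(binary_col) + 1
        except ValueError:
            raise ValueError(f"no covariate named {binary_col!r}") from None
    idx = int(binary_col)
    if not 0 <= idx < data.X.shape[1]:
        raise ValueError(f"column index {idx} out of range")
    return idx


def classify_separation(data: SurvivalDataset, binary_col) -> SeparationReport:
    """Classify a dataset as separation / near-to-separation / none.

    ``binary_col`` is a design-matrix column index or a covariate name; the
    column must be 0/1 valued.
    """
    idx = _resolve_column(data, binary_col)
    x = data.X[:, idx]
    if not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("separation diagnostic requires a 0/1 covariate column")

    delta = data.delta
    table = np.empty((2, 2), dtype=int)
    for level in (0, 1):
        for ev in (0, 1):
            table[level, ev] = int(np.sum((x == level) & (delta == ev)))
    min_cell = int(table.min())

    g0, g1 = x == 0.0, x == 1.0
    if g0.any() and g1.any():
        res = logrank_test(
            np.exp(data.y[g0]),
            np.exp(data.y[g1]),
            event_observed_A=delta[g0],
            event_observed_B=delta[g1],
        )
        p = float(res.p_value)
    else:
        p = float("nan")

    if min_cell == 0 or (np.isfinite(p) and p < 0.01):
        status = "separation"
    elif min_cell <= 5 or (np.isfinite(p) and p < 0.05):
        status = "near"
    else:
        status = "none"
    return SeparationReport(table=table, min_cell=min_cell, group_test_p=p, status=status)
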