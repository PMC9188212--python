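"""CSV ingestion and output for right-censored survival data.

Input is plain CSV with a header: one row per subject, a positive time
column (natural scale; logs are taken internally), a 0/1 event column
(1 = event, 0 = right-censored) and numeric covariate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import SurvivalDataset

__all__ = ["read_survival_csv", "write_survival_csv"]


def _rows(mask: pd.Series) -> list[int]:
    # 1-based data-row numbers (header excluded)
    return [int(i) + 1 for i in np.flatnonzero(np.asarray(mask))]


def read_survival_csv(path, time_col: str, event_col: str, covariate_cols) -> SurvivalDataset:
    """Read a survival dataset from CSV.

    Raises with offending row numbers for missing values and nonpositive
    times, and rejects non-0/1 event codes.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    covariate_cols = list(covariate_cols)
    wanted = [time_col, event_col, *covariate_cols]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    sub = df[wanted].apply(pd.to_numeric, errors="coerce")
    na_mask = sub.isna().any(axis=1)
    if na_mask.any():
        raise ValueError(f"missing/non-numeric values in rows: {_rows(na_mask)}")
    times = sub[time_col].to_numpy(dtype=float)
    bad_t = times <= 0.0
    if bad_t.any():
        raise ValueError(f"nonpositive times in rows: {_rows(pd.Series(bad_t))}")
    events = sub[event_col].to_numpy(dtype=float)
    if not np.all(np.isin(events, (0.0, 1.0))):
        bad = ~np.isin(events, (0.0, 1.0))
        raise ValueError(f"event values outside {{0, 1}} in rows: {_rows(pd.Series(bad))}")
    n = len(sub)
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in covariate_cols])
    return SurvivalDataset(
        y=np.log(times), delta=events, X=X, covariate_names=tuple(covariate_cols)
    )


def write_survival_csv(data: SurvivalDataset, path, time_col: str = "time",
                       event_col: str = "event") -> None:
    """Write a dataset to CSV (times on the natural scale, full precision)."""
    cols = {time_col: np.exp(data.y), event_col: data.delta.astype(int)}
    for j, name in enumerate(data.covariate_names, start=1):
        cols[name] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)
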