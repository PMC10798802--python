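"""CSV readers/writers and model (de)serialization.

Censored data use the standard counting-process (start-stop) layout: one row
per covariate-constant interval with columns ``id, tstart, tstop, event,
x1..xp``; a subject's intervals must tile [0, y] without gaps or overlaps and
the event flag may be 1 only on the last row.  Uncensored data are plain
``y, x1..xp`` tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expansion import CensoredRecord, CovariatePath
from .network import HazardEstimate

__all__ = [
    "read_censored_csv",
    "write_censored_csv",
    "read_uncensored_csv",
    "write_uncensored_csv",
    "save_model",
    "load_model",
]


def _covariate_columns(df):
    cols = [c for c in df.columns if c.startswith("x")]
    try:
        cols = sorted(cols, key=lambda c: int(c[1:]))
    except ValueError as exc:
        raise ValueError(f"malformed covariate column name among {cols}") from exc
    return cols


def read_censored_csv(path) -> list[CensoredRecord]:
    """Reassemble per-subject covariate paths from a start-stop CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "tstart", "tstop", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    xcols = _covariate_columns(df)
    records = []
    for sid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("tstart")
        starts = grp["tstart"].to_numpy(dtype=float)
        stops = grp["tstop"].to_numpy(dtype=float)
        if starts[0] != 0.0:
            raise ValueError(f"subject {sid}: intervals must start at 0")
        if np.any(stops <= starts):
            raise ValueError(f"subject {sid}: empty or reversed interval")
        if np.any(starts[1:] != stops[:-1]):
            raise ValueError(f"subject {sid}: intervals have gaps or overlaps")
        ev = grp["event"].to_numpy(dtype=int)
        if ev[:-1].any():
            raise ValueError(f"subject {sid}: event flagged before the last interval")
        path = CovariatePath(starts, grp[xcols].to_numpy(dtype=float))
        records.append(CensoredRecord(float(stops[-1]), int(ev[-1]), path))
    return records


def write_censored_csv(records, path, breakpoints=None):
    """Write records in the start-stop layout.

    A record's path is discretized on ``breakpoints`` (default: the pooled
    sorted observed times, i.e. the expansion grid), with each interval
    carrying the covariates the expansion would use (the path evaluated at
    the interval's stop time).
    """
    records = list(records)
    y_all = np.array([r.y for r in records])
    if breakpoints is None:
        breakpoints = np.unique(y_all)
    rows = []
    for sid, r in enumerate(records):
        stops = np.unique(np.append(breakpoints[breakpoints < r.y], r.y))
        stops = stops[stops > 0]
        starts = np.concatenate([[0.0], stops[:-1]])
        X = r.path(stops)
        for k in range(len(stops)):
            row = {
                "id": sid,
                "tstart": starts[k],
                "tstop": stops[k],
                "event": int(r.delta) if k == len(stops) - 1 else 0,
            }
            row.update({f"x{j + 1}": X[k, j] for j in range(X.shape[1])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_uncensored_csv(path):
    """Plain (y, x1..xp) table -> (X, y) arrays."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "y" not in df.columns:
        raise ValueError("missing required column 'y'")
    xcols = _covariate_columns(df)
    if not xcols:
        raise ValueError("no covariate columns (x1..xp) found")
    return df[xcols].to_numpy(dtype=float), df["y"].to_numpy(dtype=float)


def write_uncensored_csv(X, y, path):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
    df.insert(0, "y", np.asarray(y, dtype=float))
    df.to_csv(path, index=False, float_format="%.17g")


def save_model(est: HazardEstimate, path):
    Path(path).write_text(est.to_json())


def load_model(path) -> HazardEstimate:
    return HazardEstimate.from_json(Path(path).read_text())
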