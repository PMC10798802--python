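"""Counting-process data expansion.

Censored survival data with time-varying covariates are usually analysed in
the long (start-stop) format: the time axis is partitioned by the sorted
observed times ``t_1 < ... < t_m`` and every subject contributes one row per
grid point not exceeding their own observed time.  The same expansion, with a
sentinel origin instead of zero, turns an arbitrary continuous regression
response into "survival-like" data so that the full-likelihood hazard loss
applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariatePath",
    "CensoredRecord",
    "TimeGrid",
    "ExpandedTable",
    "build_time_grid",
    "expand_censored",
    "expand_uncensored",
]


@dataclass(frozen=True)
class CovariatePath:
    """Left-continuous step function of time returning a covariate vector.

    ``values[k]`` is the covariate vector on the half-open interval
    ``(breakpoints[k], breakpoints[k+1]]`` (the last segment extends to
    infinity).  Evaluation at the path origin returns the first segment's
    value, so a path with a single segment behaves as a constant.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if vals.shape[0] != bp.shape[0]:
            raise ValueError(
                f"need one value row per segment: {vals.shape[0]} rows for "
                f"{bp.shape[0]} breakpoints"
            )
        if bp.ndim != 1 or bp.size == 0:
            raise ValueError("breakpoints must be a non-empty 1-D array")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    @classmethod
    def constant(cls, x) -> "CovariatePath":
        return cls(np.array([0.0]), np.atleast_2d(np.asarray(x, dtype=float)))

    def __call__(self, t) -> np.ndarray:
        """Evaluate the path at times ``t`` (scalar or array).

        Left continuity: the value *at* a breakpoint is the value of the
        segment ending there, i.e. a jump at q is not seen until t > q.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breakpoints, t, side="left") - 1
        idx = np.clip(idx, 0, len(self.breakpoints) - 1)
        return self.values[idx]


@dataclass(frozen=True)
class CensoredRecord:
    """One right-censored observation: (observed time, event indicator, path)."""

    y: float
    delta: int
    path: CovariatePath

    def __post_init__(self):
        if not np.isfinite(self.y) or self.y < 0:
            raise ValueError(f"observed time must be finite and >= 0, got {self.y}")
        if self.delta not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.delta}")


@dataclass(frozen=True)
class TimeGrid:
    """Sorted unique observed times, with the origin convention of its mode.

    ``mode='censored'`` integrates the hazard from 0; ``mode='uncensored'``
    integrates from -inf, represented by a sentinel flag (the first interval
    carries the fixed point mass 1/n and is excluded from the loss).
    """

    points: np.ndarray
    mode: str

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size == 0:
            raise ValueError("grid needs at least one point")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if self.mode not in ("censored", "uncensored"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def origin_is_zero(self) -> bool:
        return self.mode == "censored"


def build_time_grid(times, mode: str) -> TimeGrid:
    """Partition the time axis by the unique sorted observed times.

    Tied observed times collapse to a single grid point, so all interval
    widths are strictly positive.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("cannot build a grid from no observed times")
    if not np.all(np.isfinite(times)):
        raise ValueError("observed times must be finite")
    if mode == "censored" and np.any(times < 0):
        raise ValueError("negative observed time in censored mode")
    return TimeGrid(np.unique(times), mode)


@dataclass
class ExpandedTable:
    """Row-per-(subject, grid-point) expansion of a data set.

    Arrays are aligned across rows. ``t_start`` of a subject's first row is 0
    in censored mode; in uncensored mode the first row's start is a sentinel
    (stored as NaN) and the row is flagged ``include=False`` — it carries the
    fixed 1/n mass at t_1 and never enters the loss.
    """

    subject: np.ndarray        # int, subject index of each row
    t_start: np.ndarray        # float (NaN on sentinel rows)
    t_stop: np.ndarray         # float, the grid point t_j
    delta: np.ndarray          # 0/1 per row
    covariates: np.ndarray     # (rows, p) covariates evaluated at t_stop
    include: np.ndarray        # bool, rows entering the loss
    grid: TimeGrid
    n_subjects: int
    width: np.ndarray = field(init=False)  # t_stop - t_start (0 on sentinel rows)

    def __post_init__(self):
        w = np.where(self.include, self.t_stop - np.nan_to_num(self.t_start), 0.0)
        self.width = w

    @property
    def mode(self) -> str:
        return self.grid.mode

    def __len__(self) -> int:
        return len(self.t_stop)

    def features(self) -> np.ndarray:
        """Network inputs (t_prev, t_cur, covariates) for the included rows."""
        m = self.include
        return np.column_stack(
            [self.t_start[m], self.t_stop[m], self.covariates[m]]
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.subject,
                "tstart": self.t_start,
                "tstop": self.t_stop,
                "delta": self.delta,
                "include": self.include,
            }
        )
        for k in range(self.covariates.shape[1]):
            df[f"x{k + 1}"] = self.covariates[:, k]
        return df


def _row_layout(grid_points: np.ndarray, y: np.ndarray):
    """Row bookkeeping shared by both expansions.

    Returns (subject index per row, grid index per row).  Subject i gets one
    row per grid point t_j <= y_i; y_i is always on the grid by construction.
    """
    counts = np.searchsorted(grid_points, y, side="right")
    subject = np.repeat(np.arange(len(y)), counts)
    # within-subject row ranks 0..counts_i-1 == grid indices
    gidx = np.concatenate([np.arange(c) for c in counts]) if len(y) else np.array([], int)
    return subject, gidx, counts


def expand_censored(records) -> ExpandedTable:
    """Expand censored records onto the grid of their own observed times.

    For subject i, one row per grid point ``t_j <= y_i`` with covariates
    evaluated at ``t_j`` and event indicator ``delta_ij = delta_i * 1(t_j = y_i)``.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to expand")
    dims = {r.path.dimension for r in records}
    if len(dims) != 1:
        raise ValueError(f"covariate dimension differs across records: {sorted(dims)}")
    y = np.array([r.y for r in records])
    delta_subj = np.array([r.delta for r in records])
    grid = build_time_grid(y, "censored")
    pts = grid.points

    subject, gidx, counts = _row_layout(pts, y)
    t_stop = pts[gidx]
    t_start = np.where(gidx == 0, 0.0, pts[np.maximum(gidx - 1, 0)])
    delta = (delta_subj[subject] * (t_stop == y[subject])).astype(int)
    cov = np.vstack([r.path(pts[: counts[i]]) for i, r in enumerate(records)])
    return ExpandedTable(
        subject=subject,
        t_start=t_start,
        t_stop=t_stop,
        delta=delta,
        covariates=cov,
        include=np.ones(len(t_stop), dtype=bool),
        grid=grid,
        n_subjects=len(records),
    )


def expand_uncensored(X, y) -> ExpandedTable:
    """Expand plain (response, covariates) data as in the uncensored layout.

    Every subject's final row has delta = 1 (the response is always
    "observed"); each subject's first row spans (sentinel, t_1] and is flagged
    excluded from the loss.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if y.size == 0:
        raise ValueError("no records to expand")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    grid = build_time_grid(y, "uncensored")
    pts = grid.points

    subject, gidx, _counts = _row_layout(pts, y)
    t_stop = pts[gidx]
    first = gidx == 0
    t_start = np.where(first, np.nan, pts[np.maximum(gidx - 1, 0)])
    delta = (t_stop == y[subject]).astype(int)
    return ExpandedTable(
        subject=subject,
        t_start=t_start,
        t_stop=t_stop,
        delta=delta,
        covariates=X[subject],
        include=~first,
        grid=grid,
        n_subjects=len(y),
    )
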