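"""Survival and distribution curves reconstructed from an estimated log-hazard.

Both curves are step functions on the training grid.  Because the hazard
enters through exp(h), any finite h — however badly estimated — yields a valid
monotone curve bounded in [0, 1]; no constraint on the network output is ever
needed.  Beyond the last grid point the curves are held constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expansion import TimeGrid

__all__ = [
    "StepCDF",
    "SurvivalCurve",
    "survival_curve",
    "cdf_curve",
    "conditional_mean",
    "predictive_interval",
]


@dataclass(frozen=True)
class StepCDF:
    """A step-function CDF on a fixed grid with quantile lookup."""

    times: np.ndarray
    values: np.ndarray  # F(t_j), non-decreasing, in [0, 1]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be aligned 1-D arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, y):
        """F at y: value at the largest grid point <= y (0 before the grid)."""
        idx = np.searchsorted(self.times, np.asarray(y, dtype=float), side="right")
        vals = np.concatenate([[0.0], self.values])
        return vals[idx]

    def survival(self, y):
        return 1.0 - self(y)

    def quantile(self, p):
        """Left-continuous generalized inverse min{t_j : F(t_j) >= p}.

        If no grid point reaches p (possible since F is capped below 1), the
        last grid point is returned.
        """
        p = np.asarray(p, dtype=float)
        idx = np.searchsorted(self.values, p, side="left")
        idx = np.minimum(idx, len(self.times) - 1)
        return self.times[idx]


class SurvivalCurve(StepCDF):
    """Distribution curve built from a censored-mode fit; S(0) = 1.

    Survival values are stored directly (not recovered as 1 - F) so that very
    small survival probabilities keep full precision and stay strictly
    positive.
    """

    def __init__(self, times, surv_values):
        surv_values = np.asarray(surv_values, dtype=float)
        super().__init__(times, 1.0 - surv_values)
        object.__setattr__(self, "surv_values", surv_values)

    def survival(self, y):
        idx = np.searchsorted(self.times, np.asarray(y, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.surv_values])
        return vals[idx]


# strict bounds S > 0 and F < 1 hold for any finite cumulative hazard; cap the
# exponent so floating-point underflow cannot round them onto the boundary
_CUMHAZ_CAP = 700.0
_BELOW_ONE = np.nextafter(1.0, 0.0)


def _surv_from_increments(increments):
    cumhaz = np.minimum(np.cumsum(increments), _CUMHAZ_CAP)
    return np.exp(-cumhaz)


def _h_matrix(predictor, grid_pts, t_start, x):
    x = np.asarray(x, dtype=float).ravel()
    feats = np.column_stack(
        [t_start, grid_pts, np.tile(x, (len(grid_pts), 1))]
        if x.size
        else [t_start, grid_pts]
    )
    return np.asarray(predictor(feats), dtype=float).ravel()


def survival_curve(predictor, grid: TimeGrid, x, clamp: float = 30.0) -> SurvivalCurve:
    """S(t | x) = exp(-sum_{t_j <= t} exp(h(t_{j-1}, t_j, x)) (t_j - t_{j-1})).

    ``predictor`` maps an (m, 2+p) feature matrix (t_prev, t_cur, x) to h.
    ``x`` is the covariate value used at every grid point (for a genuinely
    time-varying path, pass the path evaluated on the grid via
    :func:`survival_curve_path`).
    """
    if grid.mode != "censored":
        raise ValueError("survival_curve needs a censored-mode grid")
    pts = grid.points
    t_start = np.concatenate([[0.0], pts[:-1]])
    h = _h_matrix(predictor, pts, t_start, x)
    lam = np.exp(np.clip(h, -clamp, clamp))
    S = _surv_from_increments(lam * (pts - t_start))
    return SurvivalCurve(pts, S)


def survival_curve_path(predictor, grid: TimeGrid, path, clamp: float = 30.0) -> SurvivalCurve:
    """Variant of :func:`survival_curve` with covariates from a time-varying path."""
    if grid.mode != "censored":
        raise ValueError("survival_curve needs a censored-mode grid")
    pts = grid.points
    t_start = np.concatenate([[0.0], pts[:-1]])
    feats = np.column_stack([t_start, pts, path(pts)])
    h = np.asarray(predictor(feats), dtype=float).ravel()
    lam = np.exp(np.clip(h, -clamp, clamp))
    S = _surv_from_increments(lam * (pts - t_start))
    return SurvivalCurve(pts, S)


def cdf_curve(predictor, grid: TimeGrid, x, n_train: int, clamp: float = 30.0) -> StepCDF:
    """Conditional distribution on the training grid, uncensored mode.

    F(y | x) = 1(t_1 <= y) { 1 - (n-1)/n exp(-sum_{j>=2, t_j<=y} e^{h_j} (t_j - t_{j-1})) }

    so F(t_1 | x) = 1/n exactly (the empirical mass assigned at the smallest
    training response) and F < 1 everywhere.
    """
    if grid.mode != "uncensored":
        raise ValueError("cdf_curve needs an uncensored-mode grid")
    if n_train < 2:
        raise ValueError("need n_train >= 2")
    pts = grid.points
    if len(pts) == 1:
        return StepCDF(pts, np.array([1.0 / n_train]))
    t_start = pts[:-1]
    h = _h_matrix(predictor, pts[1:], t_start, x)
    lam = np.exp(np.clip(h, -clamp, clamp))
    cumhaz = np.minimum(
        np.concatenate([[0.0], np.cumsum(lam * (pts[1:] - t_start))]), _CUMHAZ_CAP
    )
    F = 1.0 - (1.0 - 1.0 / n_train) * np.exp(-cumhaz)
    F[0] = 1.0 / n_train  # exact empirical mass at the smallest response
    return StepCDF(pts, np.minimum(F, _BELOW_ONE))


def conditional_mean(cdf: StepCDF) -> float:
    """Riemann–Stieltjes mean  sum_j t_j (F(t_j) - F(t_{j-1}))  with F(t_0) = 0."""
    jumps = np.diff(np.concatenate([[0.0], cdf.values]))
    return float(np.sum(cdf.times * jumps))


def predictive_interval(cdf: StepCDF, level: float):
    """Equal-tailed predictive interval [Q((1-level)/2), Q((1+level)/2)]."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    lo = cdf.quantile((1.0 - level) / 2.0)
    hi = cdf.quantile((1.0 + level) / 2.0)
    return float(lo), float(hi)
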