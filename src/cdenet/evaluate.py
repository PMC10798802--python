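"""Evaluation metrics for censored and uncensored predictions.

Censored-data scores follow the inverse-probability-of-censoring-weighting
(IPCW) convention: the Kaplan-Meier estimate of the censoring-time survival
function reweights observed outcomes, so the time-dependent Brier score and
binomial log-likelihood remain unbiased under independent censoring.  The
uncensored-side metrics (squared prediction errors, predictive-interval
coverage, percentile calibration, MADE against a true conditional CDF) are
plain empirical averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "CensoringSurvival",
    "ScorePanel",
    "km_censoring",
    "c_index_td",
    "brier_score",
    "binomial_ll",
    "integrate_scores",
    "made",
    "prediction_errors",
    "coverage_rate",
    "percentile_calibration",
    "cross_validate",
]

_PROB_FLOOR = 1e-12  # keeps the binomial log-likelihood finite


@dataclass(frozen=True)
class CensoringSurvival:
    """Right-continuous Kaplan-Meier step estimate of P(C > t)."""

    times: np.ndarray   # event (i.e. censoring) times, sorted
    values: np.ndarray  # G at those times

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]

    def left_limit(self, t):
        """G(t-): the value just before t (standard IPCW weight at Y_i)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


def km_censoring(y, delta) -> CensoringSurvival:
    """Kaplan-Meier on the censoring distribution (events are 1 - delta)."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    if len(y) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(y, event_observed=1 - delta)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0  # drop the t=0 anchor row; G(0)=1 is implicit
    return CensoringSurvival(times[keep], values[keep])


def c_index_td(surv_matrix, y, delta) -> float:
    """Time-dependent concordance index.

    ``surv_matrix[i, j]`` is the predicted S(y_i | x_j).  Over comparable
    pairs (i an event, y_i < y_j) the pair counts as concordant when
    S(y_i | x_i) < S(y_i | x_j); ties in the prediction count 1/2, tied event
    times are not comparable.
    """
    S = np.asarray(surv_matrix, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    n = len(y)
    if S.shape != (n, n):
        raise ValueError(f"survival matrix must be {n}x{n}, got {S.shape}")
    comparable = (delta == 1)[:, None] & (y[:, None] < y[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    own = np.diag(S)[:, None]
    concordant = (comparable & (own < S)).sum()
    ties = (comparable & (own == S)).sum()
    return float((concordant + 0.5 * ties) / n_comp)


def _ipcw_terms(t, surv_at_t, y, delta, G: CensoringSurvival):
    surv_at_t = np.asarray(surv_at_t, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    died = (y <= t) & (delta == 1)
    alive = y > t
    w_died = G.left_limit(y)
    w_alive = G(t)
    bad = (died & (w_died == 0)) | (alive & (np.asarray(w_alive) == 0))
    if np.any(bad):
        warnings.warn(
            f"dropping {int(bad.sum())} terms with zero censoring-survival weight"
        )
        died = died & ~bad
        alive = alive & ~bad
    return surv_at_t, died, alive, w_died, w_alive


def brier_score(t, surv_at_t, y, delta, G: CensoringSurvival) -> float:
    """IPCW Brier score at time t.

    BS(t) = (1/n) sum_i [ S(t|x_i)^2 1(Y_i<=t, D_i=1)/G(Y_i-)
                          + (1-S(t|x_i))^2 1(Y_i>t)/G(t) ].
    """
    S, died, alive, w_died, w_alive = _ipcw_terms(t, surv_at_t, y, delta, G)
    n = len(y)
    total = np.sum(S[died] ** 2 / w_died[died]) + np.sum(
        (1.0 - S[alive]) ** 2 / np.broadcast_to(w_alive, (n,))[alive]
    )
    return float(total / n)


def binomial_ll(t, surv_at_t, y, delta, G: CensoringSurvival) -> float:
    """IPCW binomial log-likelihood at time t (non-positive; larger is better)."""
    S, died, alive, w_died, w_alive = _ipcw_terms(t, surv_at_t, y, delta, G)
    n = len(y)
    F_cl = np.clip(1.0 - S, _PROB_FLOOR, None)
    S_cl = np.clip(S, _PROB_FLOOR, None)
    if np.any(1.0 - S[died] < _PROB_FLOOR) or np.any(S[alive] < _PROB_FLOOR):
        warnings.warn("clipping probabilities at 1e-12 in the binomial log-likelihood")
    total = np.sum(np.log(F_cl[died]) / w_died[died]) + np.sum(
        np.log(S_cl[alive]) / np.broadcast_to(w_alive, (n,))[alive]
    )
    return float(total / n)


def integrate_scores(times, values) -> float:
    """Time-averaged score: trapezoidal integral divided by the range length."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    span = times[-1] - times[0]
    if not span > 0:
        raise ValueError("degenerate integration range")
    return float(np.trapezoid(values, times) / span)


def made(F_hat, F_true) -> float:
    """Mean absolute deviation |F_hat - F_true| where the TRUE CDF is in
    [0.001, 0.999] (the usual truncation away from the tails)."""
    F_hat = np.asarray(F_hat, dtype=float).ravel()
    F_true = np.asarray(F_true, dtype=float).ravel()
    if F_hat.shape != F_true.shape:
        raise ValueError("estimate/truth arrays must be aligned")
    keep = (F_true >= 0.001) & (F_true <= 0.999)
    if not keep.any():
        raise ValueError("no grid point has true CDF inside [0.001, 0.999]")
    return float(np.abs(F_hat[keep] - F_true[keep]).mean())


def prediction_errors(predicted, y):
    """(mean, median) of squared prediction errors."""
    sq = (np.asarray(predicted, dtype=float) - np.asarray(y, dtype=float)) ** 2
    return float(sq.mean()), float(np.median(sq))


def coverage_rate(intervals, y) -> float:
    """Fraction of responses inside their [lo, hi] predictive intervals."""
    intervals = np.asarray(intervals, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((y >= intervals[:, 0]) & (y <= intervals[:, 1])))


def percentile_calibration(cdfs, y, target_probs):
    """Empirical cumulative probabilities at estimated percentiles.

    For each target probability p, each test subject's estimated p-th
    percentile is computed from their conditional CDF, and the frequency of
    responses at or below their own percentile is returned.  With perfectly
    estimated CDFs this frequency converges to p (probability-integral
    transform).
    """
    y = np.asarray(y, dtype=float)
    target_probs = np.atleast_1d(np.asarray(target_probs, dtype=float))
    out = np.empty(len(target_probs))
    for k, p in enumerate(target_probs):
        q = np.array([float(c.quantile(p)) for c in cdfs])
        out[k] = np.mean(y <= q)
    return out


@dataclass
class ScorePanel:
    """Censored-data evaluation summary."""

    c_index: float
    ibs: float
    ibll: float
    times: np.ndarray = field(default_factory=lambda: np.array([]))
    bs_curve: np.ndarray = field(default_factory=lambda: np.array([]))
    bll_curve: np.ndarray = field(default_factory=lambda: np.array([]))


def score_panel(surv_matrix_fn, y, delta, n_grid: int = 100) -> ScorePanel:
    """All censored metrics for one test set.

    ``surv_matrix_fn(times)`` must return the S(times[i] | x_j) matrix for the
    test subjects.  BS/BLL are evaluated on ``n_grid`` equally spaced points
    spanning the observed-time range of the test set and integrated into
    time-averaged IBS / IBLL.
    """
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    G = km_censoring(y, delta)
    S_own = surv_matrix_fn(y)
    try:
        cidx = c_index_td(S_own, y, delta)
    except ValueError:
        warnings.warn("C-index undefined on this fold (no comparable pairs); skipped")
        cidx = np.nan
    if y.max() > y.min():
        tgrid = np.linspace(y.min(), y.max(), n_grid)
    else:  # degenerate test range (e.g. leave-one-out): score at the one time
        tgrid = np.array([y.min()])
    S_t = surv_matrix_fn(tgrid)
    bs = np.array([brier_score(t, S_t[k], y, delta, G) for k, t in enumerate(tgrid)])
    bll = np.array([binomial_ll(t, S_t[k], y, delta, G) for k, t in enumerate(tgrid)])
    return ScorePanel(
        c_index=cidx,
        ibs=integrate_scores(tgrid, bs) if len(tgrid) > 1 else float(bs[0]),
        ibll=integrate_scores(tgrid, bll) if len(tgrid) > 1 else float(bll[0]),
        times=tgrid,
        bs_curve=bs,
        bll_curve=bll,
    )


def cross_validate(records, fit_fn, k: int = 5, seed=None, n_grid: int = 100) -> ScorePanel:
    """k-fold cross-validated censored-data scores.

    Fold assignment is a seeded shuffle; per fold ``fit_fn(train_records)``
    returns a fitted hazard estimate (anything exposing ``survival_path``),
    the held-out fold is used purely as a test set, and the fold panels are
    averaged.
    """
    records = list(records)
    n = len(records)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n < k:
        raise ValueError("more folds than records")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % k
    panels = []
    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if len(train_idx) < 4:
            raise ValueError(f"fold {fold}: too few training records to split")
        est = fit_fn([records[i] for i in train_idx])
        test = [records[i] for i in test_idx]
        y = np.array([r.y for r in test])
        delta = np.array([r.delta for r in test])

        def surv_matrix(times, _test=test):
            return np.column_stack(
                [est.survival_path(r.path).survival(times) for r in _test]
            )

        panels.append(score_panel(surv_matrix, y, delta, n_grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        cidx = float(np.nanmean([p.c_index for p in panels]))
    return ScorePanel(
        c_index=cidx,
        ibs=float(np.mean([p.ibs for p in panels])),
        ibll=float(np.mean([p.ibll for p in panels])),
    )
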