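"""Comparison methods for uncensored data.

* ``L2Net`` — the conventional neural mean regression: same architecture and
  training protocol as the hazard network but with squared-error loss; its
  conditional distribution estimate shifts the empirical distribution of
  training residuals to the estimated conditional mean (valid only under
  i.i.d. errors uncorrelated with the mean).
* ``NadarayaWatsonCDF`` — the kernel-weighted empirical conditional CDF with
  a Gaussian product kernel and a bandwidth chosen by 5-fold cross-validation
  on CDF-indicator mean squared error.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._mlp import MLP, sgd_train, L2_LOSS
from .network import Standardizer, TrainingConfig

__all__ = [
    "L2Net",
    "NadarayaWatsonCDF",
    "fit_l2_network",
    "residual_shift_cdf",
    "nw_conditional_cdf",
    "cv_bandwidth",
]


class L2Net(BaseEstimator, RegressorMixin):
    """Mean regression by the same network/protocol, with L2 loss.

    The swapped 1:1 split and h-scale averaging are identical to the hazard
    network's protocol so that comparisons isolate the loss function.  The
    response is internally standardized for training and mapped back.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        learning_rate: float = 0.001,
        batch_size: int = 100,
        patience: int = 10,
        max_epochs: int = 500,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.random_state = random_state

    def _fit_one(self, X_tr, y_tr, X_val, y_val, seed, rng):
        net = MLP(X_tr.shape[1], self.hidden_units, rng=seed)
        # zero the output head: the initial prediction is exactly the
        # (standardized) response mean, so optimization starts at the best
        # constant fit instead of random-scale outputs
        net.views()[4][:] = 0.0
        sgd_train(
            net,
            X_tr,
            y_tr,
            X_val,
            y_val,
            L2_LOSS,
            lr=self.learning_rate,
            batch_size=min(self.batch_size, len(y_tr)),
            patience=self.patience,
            max_epochs=self.max_epochs,
            rng=rng,
        )
        return net

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n = len(y)
        if n < 4:
            raise ValueError("need at least 4 observations")
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2 :]
        self.x_std_ = Standardizer.fit(X)
        self.y_mean_, self.y_sd_ = float(y.mean()), float(y.std() or 1.0)
        Z = self.x_std_(X)
        yz = (y - self.y_mean_) / self.y_sd_
        seeds = rng.integers(2**31, size=2)
        self.nets_ = [
            self._fit_one(Z[a], yz[a], Z[b], yz[b], int(seeds[0]), rng),
            self._fit_one(Z[b], yz[b], Z[a], yz[a], int(seeds[1]), rng),
        ]
        self.residuals_ = np.sort(y - self.predict(X))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "nets_")
        X = check_array(X)
        Z = self.x_std_(X)
        out = sum(net.forward(Z) for net in self.nets_) / len(self.nets_)
        return out * self.y_sd_ + self.y_mean_

    def predict_cdf_value(self, X, ys):
        """Residual-shift CDF F(ys[j] | X[i]): empirical CDF of the training
        residuals evaluated at ys[j] - m_hat(X[i])."""
        m = self.predict(X)
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        pos = np.searchsorted(self.residuals_, ys[None, :] - m[:, None], side="right")
        return pos / len(self.residuals_)

    def predict_interval(self, X, level: float = 0.9):
        """Equal-tailed intervals from the shifted residual distribution."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        m = self.predict(X)
        lo = np.quantile(self.residuals_, (1 - level) / 2)
        hi = np.quantile(self.residuals_, (1 + level) / 2)
        return np.column_stack([m + lo, m + hi])


def fit_l2_network(X, y, config: TrainingConfig | None = None) -> L2Net:
    """Functional wrapper: fit the L2 baseline with a TrainingConfig."""
    config = config or TrainingConfig()
    return L2Net(
        hidden_units=config.nodes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        patience=config.patience,
        max_epochs=config.max_epochs,
        random_state=config.seed,
    ).fit(X, y)


def residual_shift_cdf(model: L2Net, x, y):
    """F(y | x) from a fitted L2 baseline (scalar-friendly wrapper)."""
    val = model.predict_cdf_value(np.atleast_2d(x), y)
    return float(val[0, 0]) if np.isscalar(y) else val[0]


class NadarayaWatsonCDF(BaseEstimator):
    """Kernel conditional CDF  F(y|x) = sum_i K_h(x - x_i) 1(y_i <= y) / sum_i K_h(x - x_i).

    Gaussian product kernel; ``bandwidth`` may be a positive scalar/vector
    (one per covariate) or None, in which case it is selected by k-fold
    cross-validation over ``cv_grid`` scale factors applied to the rule-of-
    thumb per-dimension bandwidth std(x_d) n^(-1/5).
    """

    def __init__(self, bandwidth=None, cv_folds: int = 5, cv_grid=None,
                 random_state: int | None = None):
        self.bandwidth = bandwidth
        self.cv_folds = cv_folds
        self.cv_grid = cv_grid
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.X_, self.y_ = X, y
        if self.bandwidth is not None:
            bw = np.broadcast_to(
                np.asarray(self.bandwidth, dtype=float), (X.shape[1],)
            ).copy()
            if np.any(bw <= 0):
                raise ValueError("bandwidths must be positive")
            self.bandwidth_ = bw
        else:
            self.bandwidth_ = cv_bandwidth(
                X, y, k=self.cv_folds, grid=self.cv_grid, seed=self.random_state
            )
        self.n_features_in_ = X.shape[1]
        return self

    def predict_cdf_value(self, X, ys):
        """(len(X), len(ys)) matrix of conditional CDF values."""
        check_is_fitted(self, "bandwidth_")
        X = check_array(X)
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        W = _gauss_weights(X, self.X_, self.bandwidth_)
        mass = W.sum(axis=1)
        if np.any(mass <= 0):
            raise ValueError("zero kernel mass at a query point; enlarge the bandwidth")
        ind = (self.y_[:, None] <= ys[None, :]).astype(float)
        return (W @ ind) / mass[:, None]


def _gauss_weights(Xq, X, bw):
    d = (Xq[:, None, :] - X[None, :, :]) / bw
    return np.exp(-0.5 * np.einsum("qnd,qnd->qn", d, d))


def nw_conditional_cdf(est: NadarayaWatsonCDF, x, y):
    """Scalar-friendly wrapper around :meth:`NadarayaWatsonCDF.predict_cdf_value`."""
    val = est.predict_cdf_value(np.atleast_2d(x), y)
    return float(val[0, 0]) if np.isscalar(y) else val[0]


DEFAULT_BW_FACTORS = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)


def cv_bandwidth(X, y, k: int = 5, grid=None, seed=None, n_ygrid: int = 21):
    """Bandwidth by k-fold CV on CDF-indicator mean squared error.

    For each candidate (a scale factor times the rule-of-thumb per-dimension
    bandwidth), the held-out squared error between 1(y_held <= y) and
    F_hat(y | x_held) is averaged over ``n_ygrid`` evenly spaced y values
    spanning the training range.  Ties prefer the smaller bandwidth.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    factors = np.sort(np.asarray(grid if grid is not None else DEFAULT_BW_FACTORS, dtype=float))
    if factors.size == 0:
        raise ValueError("empty bandwidth grid")
    base = X.std(axis=0) * n ** (-0.2)
    base = np.where(base < 1e-12, 1.0, base)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % k
    ygrid = np.linspace(y.min(), y.max(), n_ygrid)

    best_f, best_err = None, np.inf
    for f in factors:
        bw = f * base
        errs = []
        for fold in range(k):
            te = assignment == fold
            tr = ~te
            W = _gauss_weights(X[te], X[tr], bw)
            mass = W.sum(axis=1)
            if np.any(mass <= 0):
                errs = None
                break
            ind_tr = (y[tr][:, None] <= ygrid[None, :]).astype(float)
            F = (W @ ind_tr) / mass[:, None]
            ind_te = (y[te][:, None] <= ygrid[None, :]).astype(float)
            errs.append(np.mean((ind_te - F) ** 2))
        if errs is None:
            continue
        err = float(np.mean(errs))
        if err < best_err - 1e-15:
            best_err, best_f = err, f
    if best_f is None:
        raise ValueError("every candidate bandwidth left a query with zero kernel mass")
    return best_f * base
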