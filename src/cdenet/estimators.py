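"""Scikit-learn style estimators wrapping the hazard-network protocol.

``NeuralCDF`` handles plain (X, y) regression data and estimates the whole
conditional distribution F(y | x); ``NeuralHazard`` handles right-censored
records with (possibly time-varying) covariates and estimates the conditional
survival function S(t | x).  Both compose with sklearn model selection via
``get_params`` / ``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .curves import conditional_mean, predictive_interval
from .expansion import CensoredRecord
from .network import TrainingConfig, fit_swap_average

__all__ = ["NeuralCDF", "NeuralHazard"]


def _config_from(est, n_obs) -> TrainingConfig:
    seed = est.random_state
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    return TrainingConfig(
        nodes=est.hidden_units,
        learning_rate=est.learning_rate,
        batch_size=min(est.batch_size, max(1, n_obs)),
        patience=est.patience,
        max_epochs=est.max_epochs,
        seed=int(seed),
        clamp=est.clamp,
    )


class NeuralCDF(BaseEstimator, RegressorMixin):
    """Conditional distribution estimator for an uncensored continuous response.

    The response axis is partitioned by the sorted training responses, the
    data are expanded row-per-(subject, grid point), and a small network is
    trained on the full-likelihood hazard loss.  The fitted object exposes the
    whole conditional CDF; ``predict`` integrates it into a conditional mean,
    so the estimator scores like a regressor while also providing calibrated
    quantiles and predictive intervals.

    Parameters
    ----------
    hidden_units : width of the two hidden ReLU layers.
    learning_rate, batch_size, patience, max_epochs : Adam / early-stopping
        settings; training always uses the swapped 1:1 split protocol.
    clamp : symmetric bound applied to h inside exp() during loss evaluation.
    random_state : seed for the split, the weight init and the batch order.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        learning_rate: float = 0.001,
        batch_size: int = 100,
        patience: int = 10,
        max_epochs: int = 500,
        clamp: float = 30.0,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.clamp = clamp
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.hazard_ = fit_swap_average((X, y), _config_from(self, len(y)))
        self.grid_ = self.hazard_.grid
        self.n_features_in_ = X.shape[1]
        return self

    # -- distribution access ---------------------------------------------------
    def predict_cdf(self, X):
        """Step-function conditional CDFs, one per row of X."""
        check_is_fitted(self, "hazard_")
        X = check_array(X)
        return [self.hazard_.cdf(x) for x in X]

    def predict(self, X):
        """Conditional means via the Riemann–Stieltjes sum over the CDF."""
        return np.array([conditional_mean(c) for c in self.predict_cdf(X)])

    def predict_quantile(self, X, p):
        """Conditional p-th quantiles (generalized inverse of the CDF)."""
        return np.array([float(c.quantile(p)) for c in self.predict_cdf(X)])

    def predict_interval(self, X, level: float = 0.9):
        """(n, 2) array of equal-tailed predictive intervals."""
        return np.array(
            [predictive_interval(c, level) for c in self.predict_cdf(X)]
        )


class NeuralHazard(BaseEstimator):
    """Conditional hazard / survival estimator for right-censored records.

    ``fit`` takes a list of :class:`~cdenet.expansion.CensoredRecord`; the
    network input is (t_prev, t_cur, covariates at t_cur), so time-varying
    covariate paths are handled natively through the expanded data layout.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        learning_rate: float = 0.001,
        batch_size: int = 100,
        patience: int = 10,
        max_epochs: int = 500,
        clamp: float = 30.0,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.clamp = clamp
        self.random_state = random_state

    def fit(self, records, y=None):
        records = list(records)
        if not all(isinstance(r, CensoredRecord) for r in records):
            raise TypeError("fit expects a list of CensoredRecord")
        self.hazard_ = fit_swap_average(records, _config_from(self, len(records)))
        self.grid_ = self.hazard_.grid
        self.n_features_in_ = records[0].path.dimension
        return self

    def predict_survival(self, X):
        """Survival curves for constant covariate vectors (one per row of X)."""
        check_is_fitted(self, "hazard_")
        X = check_array(X)
        return [self.hazard_.survival(x) for x in X]

    def predict_survival_path(self, path):
        """Survival curve for a time-varying covariate path."""
        check_is_fitted(self, "hazard_")
        return self.hazard_.survival_path(path)

    def survival_matrix(self, times, paths_or_X):
        """S(times[i] | subject j) matrix used by the censored-data metrics."""
        check_is_fitted(self, "hazard_")
        times = np.asarray(times, dtype=float)
        if hasattr(paths_or_X, "ndim"):
            curves = self.predict_survival(paths_or_X)
        else:
            curves = [self.hazard_.survival_path(p) for p in paths_or_X]
        return np.column_stack([c.survival(times) for c in curves])
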