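"""Training protocol: configuration, early stopping, swap-and-average.

The estimation target is the unconstrained log-hazard h(t_prev, t_cur, x); a
two-hidden-layer ReLU network is trained by minibatch Adam on the discretized
likelihood loss.  The data are split 1:1 into a training and a validation
half, each expanded on its own observed-time grid; training stops when the
validation loss has not improved for ``patience`` consecutive epochs and the
best-epoch weights are restored.  The fit is repeated with the two halves
swapped, and the final predictor averages the two networks' h outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np

from ._mlp import MLP, sgd_train, HAZARD_LOSS
from .curves import StepCDF, SurvivalCurve, cdf_curve, survival_curve, survival_curve_path
from .expansion import (
    CensoredRecord,
    ExpandedTable,
    TimeGrid,
    build_time_grid,
    expand_censored,
    expand_uncensored,
)

__all__ = [
    "TrainingConfig",
    "FitResult",
    "HazardEstimate",
    "make_network",
    "train_early_stopping",
    "fit_swap_average",
    "tune_hyperparameters",
    "DEFAULT_TUNING_GRID",
]

#: hyperparameter grid used for tuning on real data: 3 x 4 x 3 combinations
DEFAULT_TUNING_GRID = {
    "nodes": [64, 128, 256],
    "learning_rate": [0.1, 0.01, 0.001, 0.0001],
    "batch_size": [64, 128, 256],
}


@dataclass
class TrainingConfig:
    """Network and optimizer settings (defaults follow the simulation protocol)."""

    hidden_layers: int = 2
    nodes: int = 64
    learning_rate: float = 0.001
    batch_size: int = 100
    patience: int = 10
    max_epochs: int = 500
    seed: int | None = None
    clamp: float = 30.0

    def __post_init__(self):
        if self.hidden_layers != 2:
            raise ValueError("only the two-hidden-layer architecture is supported")
        for name in ("nodes", "learning_rate", "batch_size", "patience", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "TrainingConfig":
        d = asdict(self)
        d.update(kw)
        return TrainingConfig(**d)


@dataclass
class Standardizer:
    """Column-wise (x - mean) / sd transform fitted on training features."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, F: np.ndarray) -> "Standardizer":
        mean = F.mean(axis=0)
        sd = F.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean, sd)

    def __call__(self, F: np.ndarray) -> np.ndarray:
        return (np.asarray(F, dtype=float) - self.mean) / self.sd


@dataclass
class HazardEstimate:
    """A trained (possibly averaged) map (t_prev, t_cur, x) -> log-hazard h.

    Calling it on a raw feature matrix standardizes the inputs and averages
    the member networks' outputs on the h scale.  ``grid`` and ``n_train``
    are what curve reconstruction needs.
    """

    nets: list
    standardizer: Standardizer
    grid: TimeGrid
    n_train: int
    clamp: float = 30.0

    def __call__(self, features) -> np.ndarray:
        Z = self.standardizer(np.atleast_2d(features))
        out = self.nets[0].forward(Z)
        for net in self.nets[1:]:
            out = out + net.forward(Z)
        return out / len(self.nets)

    # -- curve reconstruction -------------------------------------------------
    def survival(self, x) -> SurvivalCurve:
        return survival_curve(self, self.grid, x, clamp=self.clamp)

    def survival_path(self, path) -> SurvivalCurve:
        return survival_curve_path(self, self.grid, path, clamp=self.clamp)

    def cdf(self, x) -> StepCDF:
        return cdf_curve(self, self.grid, x, self.n_train, clamp=self.clamp)

    # -- serialization --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "hazard_estimate",
                "mode": self.grid.mode,
                "grid": self.grid.points.tolist(),
                "n_train": self.n_train,
                "clamp": self.clamp,
                "standardizer": {
                    "mean": self.standardizer.mean.tolist(),
                    "sd": self.standardizer.sd.tolist(),
                },
                "nets": [
                    {
                        "input_dim": net.input_dim,
                        "hidden": net.hidden,
                        "theta": net.theta.tolist(),
                    }
                    for net in self.nets
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "HazardEstimate":
        obj = json.loads(text)
        if obj.get("kind") != "hazard_estimate":
            raise ValueError("not a serialized hazard estimate")
        nets = []
        for spec in obj["nets"]:
            net = MLP(spec["input_dim"], spec["hidden"], rng=0)
            net.theta = np.asarray(spec["theta"], dtype=float)
            nets.append(net)
        std = Standardizer(
            np.asarray(obj["standardizer"]["mean"], dtype=float),
            np.asarray(obj["standardizer"]["sd"], dtype=float),
        )
        grid = TimeGrid(np.asarray(obj["grid"], dtype=float), obj["mode"])
        return cls(nets, std, grid, int(obj["n_train"]), float(obj["clamp"]))


@dataclass
class FitResult:
    """Outcome of one early-stopped training run."""

    hazard: HazardEstimate
    train_loss: np.ndarray
    val_loss: np.ndarray
    stopped_epoch: int
    best_epoch: int
    best_val_loss: float = field(default=np.nan)


def make_network(input_dim: int, config: TrainingConfig | None = None) -> MLP:
    """Untrained fully-connected net with the configured width and a scalar output."""
    config = config or TrainingConfig()
    if input_dim < 1:
        raise ValueError(f"input_dim must be >= 1, got {input_dim}")
    return MLP(input_dim, config.nodes, rng=config.seed)


def _table_training_arrays(table: ExpandedTable):
    """(features, widths, deltas, subject-count norm) of a table's loss rows."""
    m = table.include
    F = table.features()
    return F, table.width[m], table.delta[m].astype(float), table.n_subjects


def train_early_stopping(
    train: ExpandedTable,
    val: ExpandedTable,
    config: TrainingConfig | None = None,
    standardizer: Standardizer | None = None,
) -> FitResult:
    """Fit one network on an expanded training table, early-stopped on ``val``.

    Both tables must share mode and covariate dimension.  The returned
    estimate's reconstruction grid is the training table's grid.
    """
    config = config or TrainingConfig()
    if train.mode != val.mode:
        raise ValueError("train and validation tables have different modes")
    if train.covariates.shape[1] != val.covariates.shape[1]:
        raise ValueError("train and validation covariate dimensions differ")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty expanded table")

    F_tr, w_tr, d_tr, n_tr = _table_training_arrays(train)
    F_val, w_val, d_val, n_val = _table_training_arrays(val)
    std = standardizer or Standardizer.fit(F_tr)
    rng = np.random.default_rng(config.seed)
    net = make_network(F_tr.shape[1], config.replace(seed=int(rng.integers(2**31))))
    # start the output bias at the aggregate log event rate (events per unit
    # exposure), so optimization begins at the best constant hazard instead of
    # e^h = 1; the per-interval likelihood minimizer has exactly this form
    total_width = w_tr.sum()
    if total_width > 0 and d_tr.sum() > 0:
        net.views()[5][0] = np.log(d_tr.sum() / total_width)
    hist = sgd_train(
        net,
        std(F_tr),
        (w_tr, d_tr),
        std(F_val),
        (w_val, d_val),
        HAZARD_LOSS,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        patience=config.patience,
        max_epochs=config.max_epochs,
        rng=rng,
        clamp=config.clamp,
        norm_tr=n_tr,
        norm_val=n_val,
    )
    est = HazardEstimate([net], std, train.grid, n_tr, clamp=config.clamp)
    return FitResult(
        hazard=est,
        train_loss=hist["train_loss"],
        val_loss=hist["val_loss"],
        stopped_epoch=hist["stopped_epoch"],
        best_epoch=hist["best_epoch"],
        best_val_loss=hist["best_val_loss"],
    )


def _expand(data, half_idx=None):
    """Expand records (censored) or an (X, y) pair (uncensored)."""
    if isinstance(data, tuple):
        X, y = data
        if half_idx is not None:
            X, y = np.asarray(X)[half_idx], np.asarray(y)[half_idx]
        return expand_uncensored(X, y)
    records = list(data)
    if half_idx is not None:
        records = [records[i] for i in half_idx]
    return expand_censored(records)


def fit_swap_average(data, config: TrainingConfig | None = None) -> HazardEstimate:
    """Full estimation protocol: 1:1 split, two early-stopped fits with the
    roles of the halves swapped, h outputs averaged.

    ``data`` is either a list of :class:`CensoredRecord` or an ``(X, y)``
    tuple of uncensored covariates and responses.  The returned estimate
    reconstructs curves on the pooled grid of all observed times.
    """
    config = config or TrainingConfig()
    if isinstance(data, tuple):
        n = len(np.asarray(data[1]))
        all_times = np.asarray(data[1], dtype=float)
        mode = "uncensored"
    else:
        data = list(data)
        n = len(data)
        all_times = np.array([r.y for r in data])
        mode = "censored"
    if n < 4:
        raise ValueError("need at least 4 observations for a swapped 1:1 split")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]
    table_a = _expand(data, half_a)
    table_b = _expand(data, half_b)

    # one standardizer from the pooled loss rows so both nets share inputs
    F_pool = np.vstack([table_a.features(), table_b.features()])
    std = Standardizer.fit(F_pool)

    seed_a, seed_b = rng.integers(2**31, size=2)
    fit_a = train_early_stopping(
        table_a, table_b, config.replace(seed=int(seed_a)), standardizer=std
    )
    fit_b = train_early_stopping(
        table_b, table_a, config.replace(seed=int(seed_b)), standardizer=std
    )

    grid = build_time_grid(all_times, mode)
    return HazardEstimate(
        nets=fit_a.hazard.nets + fit_b.hazard.nets,
        standardizer=std,
        grid=grid,
        n_train=n,
        clamp=config.clamp,
    )


def tune_hyperparameters(
    data,
    grid: dict | None = None,
    config: TrainingConfig | None = None,
) -> TrainingConfig:
    """Exhaustive grid search over nodes x learning rate x batch size.

    Each candidate is trained once on a fixed seeded 1:1 split and scored by
    its best validation loss; ties are broken by grid order (nodes outermost,
    batch size innermost).
    """
    grid = grid or DEFAULT_TUNING_GRID
    config = config or TrainingConfig()
    nodes = list(grid.get("nodes", [config.nodes]))
    lrs = list(grid.get("learning_rate", [config.learning_rate]))
    batches = list(grid.get("batch_size", [config.batch_size]))
    if not nodes or not lrs or not batches:
        raise ValueError("empty hyperparameter grid")

    rng = np.random.default_rng(config.seed)
    if isinstance(data, tuple):
        n = len(np.asarray(data[1]))
    else:
        data = list(data)
        n = len(data)
    perm = rng.permutation(n)
    table_tr = _expand(data, perm[: n // 2])
    table_val = _expand(data, perm[n // 2 :])
    fit_seed = int(rng.integers(2**31))

    best = None
    best_loss = np.inf
    for nd, lr, bs in product(nodes, lrs, batches):
        cand = config.replace(nodes=nd, learning_rate=lr, batch_size=bs, seed=fit_seed)
        try:
            res = train_early_stopping(table_tr, table_val, cand)
            score = res.best_val_loss
        except FloatingPointError:
            score = np.inf  # diverged candidate (e.g. lr too large)
        if score < best_loss:
            best_loss = score
            best = cand
    if best is None:
        raise RuntimeError("every hyperparameter candidate diverged")
    return best
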