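"""Minimal fully-connected network with Adam, written on numpy + numba.

The model is deliberately small (two hidden ReLU layers, linear scalar
output), so a dependency-free implementation keeps the whole training loop —
including the nonstandard likelihood loss — transparent and deterministic.
Weights use He initialization; every layer carries a bias (intercept) term.
The minibatch loop is JIT-compiled since expanded tables have O(n^2) rows.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["MLP", "sgd_train", "HAZARD_LOSS", "L2_LOSS"]

HAZARD_LOSS = 0  # rowwise exp(h)*width - h*delta, aux = (width, delta)
L2_LOSS = 1      # rowwise (h - y)^2, aux = y


class MLP:
    """Feed-forward net: input -> ReLU(hidden) -> ReLU(hidden) -> linear scalar.

    Parameters live in a single flat vector ``theta`` (layer views are
    reconstructed on demand), which keeps the optimizer state trivially
    serializable and the JIT-compiled update loop simple.
    """

    def __init__(self, input_dim: int, hidden: int = 64, rng=None):
        if input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {input_dim}")
        if hidden < 1:
            raise ValueError(f"hidden width must be >= 1, got {hidden}")
        rng = np.random.default_rng(rng)
        self.input_dim = int(input_dim)
        self.hidden = int(hidden)
        d, H = self.input_dim, self.hidden
        self.theta = np.zeros(d * H + H + H * H + H + H + 1)
        W1, b1, W2, b2, W3, b3 = self.views()
        W1[:] = rng.normal(0.0, np.sqrt(2.0 / d), (d, H))
        W2[:] = rng.normal(0.0, np.sqrt(2.0 / H), (H, H))
        W3[:] = rng.normal(0.0, np.sqrt(2.0 / H), H)

    def views(self):
        d, H = self.input_dim, self.hidden
        t = self.theta
        o = 0
        W1 = t[o : o + d * H].reshape(d, H); o += d * H
        b1 = t[o : o + H]; o += H
        W2 = t[o : o + H * H].reshape(H, H); o += H * H
        b2 = t[o : o + H]; o += H
        W3 = t[o : o + H]; o += H
        b3 = t[o : o + 1]
        return W1, b1, W2, b2, W3, b3

    @property
    def n_params(self) -> int:
        return self.theta.size

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W1, b1, W2, b2, W3, b3 = self.views()
        A1 = np.maximum(X @ W1 + b1, 0.0)
        A2 = np.maximum(A1 @ W2 + b2, 0.0)
        return A2 @ W3 + b3[0]

    def __call__(self, X):
        return self.forward(X)

    def copy_params(self) -> np.ndarray:
        return self.theta.copy()

    def set_params_(self, theta: np.ndarray):
        self.theta = np.asarray(theta, dtype=float).copy()


@njit(cache=True)
def _train_epoch(X, aux1, aux2, loss_kind, order, bs, theta, m, v, step0,
                 lr, lr_decay, clamp, d, H):
    """One pass of minibatch Adam over ``order``; mutates theta/m/v in place.

    The learning rate decays per update as lr / (1 + lr_decay * step)
    (inverse-time decay of the initial rate).
    """
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    o = 0
    W1 = theta[o : o + d * H].reshape(d, H); o += d * H
    ob1 = o; o += H
    W2 = theta[o : o + H * H].reshape(H, H); o += H * H
    ob2 = o; o += H
    oW3 = o; o += H
    ob3 = o
    b1 = theta[ob1 : ob1 + H]
    b2 = theta[ob2 : ob2 + H]
    W3 = theta[oW3 : oW3 + H]
    grad = np.empty_like(theta)
    ZERO = X.dtype.type(0.0)
    n = X.shape[0]
    step = step0
    loss_sum = 0.0
    for lo in range(0, n, bs):
        hi = min(lo + bs, n)
        nb = hi - lo
        Xb = np.empty((nb, d), dtype=X.dtype)
        a1b = np.empty(nb, dtype=X.dtype)
        a2b = np.empty(nb, dtype=X.dtype)
        for k in range(nb):
            r = order[lo + k]
            for c in range(d):
                Xb[k, c] = X[r, c]
            a1b[k] = aux1[r]
            a2b[k] = aux2[r]
        Z1 = np.dot(Xb, W1)
        for k in range(nb):
            for c in range(H):
                Z1[k, c] += b1[c]
        A1 = np.maximum(Z1, ZERO)
        Z2 = np.dot(A1, W2)
        for k in range(nb):
            for c in range(H):
                Z2[k, c] += b2[c]
        A2 = np.maximum(Z2, ZERO)
        h = np.dot(A2, W3) + theta[ob3]
        # d(mean batch loss)/dh, accumulating the rowwise loss on the side
        g = np.empty(nb, dtype=X.dtype)
        if loss_kind == 0:
            for k in range(nb):
                hk = min(max(h[k], -clamp), clamp)
                ehk = np.exp(hk)
                loss_sum += ehk * a1b[k] - h[k] * a2b[k]
                g[k] = (ehk * a1b[k] - a2b[k]) / nb
        else:
            for k in range(nb):
                resid = h[k] - a1b[k]
                loss_sum += resid * resid
                g[k] = 2.0 * resid / nb
        # backward
        gb3 = g.sum()
        gW3 = np.dot(np.ascontiguousarray(A2.T), g)
        G2 = np.empty((nb, H), dtype=X.dtype)
        for k in range(nb):
            gk = g[k]
            for c in range(H):
                G2[k, c] = gk * W3[c] if Z2[k, c] > 0.0 else 0.0
        gW2 = np.dot(np.ascontiguousarray(A1.T), G2)
        gb2 = G2.sum(axis=0)
        G1 = np.dot(G2, np.ascontiguousarray(W2.T))
        for k in range(nb):
            for c in range(H):
                if Z1[k, c] <= 0.0:
                    G1[k, c] = 0.0
        gW1 = np.dot(np.ascontiguousarray(Xb.T), G1)
        gb1 = G1.sum(axis=0)
        # pack
        o = 0
        grad[o : o + d * H] = gW1.ravel(); o += d * H
        grad[o : o + H] = gb1; o += H
        grad[o : o + H * H] = gW2.ravel(); o += H * H
        grad[o : o + H] = gb2; o += H
        grad[o : o + H] = gW3; o += H
        grad[o] = gb3
        # Adam with inverse-time decayed step size
        step += 1
        lr_t = lr / (1.0 + lr_decay * step)
        c1 = 1.0 - beta1 ** step
        c2 = 1.0 - beta2 ** step
        for j in range(theta.size):
            gj = grad[j]
            m[j] = beta1 * m[j] + (1.0 - beta1) * gj
            v[j] = beta2 * v[j] + (1.0 - beta2) * gj * gj
            theta[j] -= lr_t * (m[j] / c1) / (np.sqrt(v[j] / c2) + eps)
    return step, loss_sum


def _rowwise_loss(h, aux1, aux2, loss_kind, clamp):
    if loss_kind == HAZARD_LOSS:
        return np.exp(np.clip(h, -clamp, clamp)) * aux1 - h * aux2
    return (h - aux1) ** 2


def _val_loss32(theta_views, X32, aux1, aux2, loss_kind, clamp):
    """Full-batch loss in float32 (expanded tables make this the hot path)."""
    W1, b1, W2, b2, W3, b3 = theta_views
    A1 = np.maximum(X32 @ W1 + b1, np.float32(0.0))
    A2 = np.maximum(A1 @ W2 + b2, np.float32(0.0))
    h = (A2 @ W3 + b3[0]).astype(float)
    return float(_rowwise_loss(h, aux1, aux2, loss_kind, clamp).sum())


def sgd_train(
    net: MLP,
    X_tr,
    aux_tr,
    X_val,
    aux_val,
    loss_kind: int,
    *,
    lr=1e-3,
    batch_size=100,
    patience=10,
    max_epochs=500,
    rng=None,
    clamp=30.0,
    norm_tr=None,
    norm_val=None,
    lr_decay=4e-5,
):
    """Minibatch Adam with early stopping on a held-out validation loss.

    ``aux_*`` is a (width, delta) pair for the likelihood loss or the response
    vector for L2.  Validation loss is evaluated full-batch after every epoch;
    training stops once it has failed to improve for ``patience`` consecutive
    epochs, and the best-epoch weights are restored.  ``norm_*`` divides the
    summed loss (defaults to the number of rows; pass the subject count to
    match the likelihood normalization).

    Returns a history dict with per-epoch train/validation losses and the
    epoch whose weights were kept.
    """
    rng = np.random.default_rng(rng)
    # training runs in float32 throughout: the expanded tables make both the
    # minibatch loop and the per-epoch validation pass the hot path, and
    # single precision is ample for SGD
    X_tr = np.ascontiguousarray(X_tr, dtype=np.float32)
    X_val32 = np.ascontiguousarray(X_val, dtype=np.float32)
    if X_tr.shape[0] == 0 or X_val32.shape[0] == 0:
        raise ValueError("empty training or validation set")
    if loss_kind == HAZARD_LOSS:
        a1_tr, a2_tr = (np.ascontiguousarray(a, dtype=np.float32) for a in aux_tr)
        a1_val, a2_val = (np.asarray(a, dtype=float) for a in aux_val)
    else:
        a1_tr = np.ascontiguousarray(aux_tr, dtype=np.float32)
        a2_tr = np.zeros_like(a1_tr)
        a1_val = np.asarray(aux_val, dtype=float)
        a2_val = np.zeros_like(a1_val)
    n_rows = X_tr.shape[0]
    norm_tr = float(norm_tr if norm_tr is not None else n_rows)
    norm_val = float(norm_val if norm_val is not None else X_val32.shape[0])

    theta32 = net.theta.astype(np.float32)
    m = np.zeros_like(theta32)
    v = np.zeros_like(theta32)
    step = 0
    best_val = np.inf
    best_theta = theta32.copy()
    best_epoch = 0
    bad = 0
    train_hist, val_hist = [], []

    def _views32():
        d, H = net.input_dim, net.hidden
        o = 0
        W1 = theta32[o : o + d * H].reshape(d, H); o += d * H
        b1 = theta32[o : o + H]; o += H
        W2 = theta32[o : o + H * H].reshape(H, H); o += H * H
        b2 = theta32[o : o + H]; o += H
        W3 = theta32[o : o + H]; o += H
        b3 = theta32[o : o + 1]
        return W1, b1, W2, b2, W3, b3

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n_rows)
        step, ep_loss_sum = _train_epoch(
            X_tr, a1_tr, a2_tr, loss_kind, order, int(batch_size),
            theta32, m, v, step, float(lr), float(lr_decay), float(clamp),
            net.input_dim, net.hidden,
        )
        # running (pre-update, within-epoch) training loss, as minibatch
        # trainers conventionally report it
        tr_loss = float(ep_loss_sum / norm_tr)
        val_loss = (
            _val_loss32(_views32(), X_val32, a1_val, a2_val, loss_kind, clamp)
            / norm_val
        )
        if not np.isfinite(val_loss) or not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(train={tr_loss}, val={val_loss}); try a smaller learning rate"
            )
        train_hist.append(tr_loss)
        val_hist.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_theta = theta32.copy()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break

    net.set_params_(best_theta.astype(float))
    return {
        "train_loss": np.array(train_hist),
        "val_loss": np.array(val_hist),
        "stopped_epoch": len(val_hist),
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
    }
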