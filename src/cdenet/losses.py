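"""Discretized full-likelihood losses.

With ``h = log lambda`` evaluated rowwise on an expanded table, the negative
log likelihood per subject discretizes to

    (1/n) sum_i sum_{t_j <= y_i} [ exp(h_ij) (t_j - t_{j-1}) - h_ij delta_ij ]

with t_0 = 0 for censored data.  For uncensored data the first interval
carries a fixed 1/n point mass, so the sum starts at j = 2 and the constant
-log(1 - 1/n) term is dropped (it does not depend on h).
"""

from __future__ import annotations

import numpy as np

from .expansion import ExpandedTable

__all__ = ["censored_loss", "uncensored_loss", "H_CLAMP"]

#: default clamp applied to h inside exp() to keep the loss finite while the
#: unconstrained network output transiently explodes during training
H_CLAMP = 30.0


def _rowwise_terms(h, width, delta, clamp):
    h = np.asarray(h, dtype=float)
    hc = np.clip(h, -clamp, clamp)
    return np.exp(hc) * width - h * delta


def censored_loss(h_values, table: ExpandedTable, clamp: float = H_CLAMP) -> float:
    """Average (over subjects) discretized negative log likelihood, censored mode."""
    if table.mode != "censored":
        raise ValueError("table is not in censored mode")
    h_values = np.asarray(h_values, dtype=float)
    if h_values.shape != table.t_stop.shape:
        raise ValueError(
            f"{h_values.shape[0] if h_values.ndim else 1} h values for "
            f"{len(table)} table rows"
        )
    terms = _rowwise_terms(h_values, table.width, table.delta, clamp)
    return float(terms.sum() / table.n_subjects)


def uncensored_loss(h_values, table: ExpandedTable, clamp: float = H_CLAMP) -> float:
    """As :func:`censored_loss` but summing included rows only (j >= 2).

    ``h_values`` may be given either for all table rows or for the included
    rows only; the constant -log(1 - 1/n) term is omitted.
    """
    if table.mode != "uncensored":
        raise ValueError("table is not in uncensored mode")
    h_values = np.asarray(h_values, dtype=float)
    inc = table.include
    if h_values.shape == table.t_stop.shape:
        h_inc = h_values[inc]
    elif h_values.shape == (int(inc.sum()),):
        h_inc = h_values
    else:
        raise ValueError(
            f"h has length {h_values.size}; expected {len(table)} (all rows) "
            f"or {int(inc.sum())} (included rows)"
        )
    terms = _rowwise_terms(h_inc, table.width[inc], table.delta[inc], clamp)
    return float(terms.sum() / table.n_subjects)
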