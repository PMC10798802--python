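import numpy as np
import pytest

from cdenet.expansion import CensoredRecord, CovariatePath


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(y, delta, X=None):
    """Censored records with constant covariates (1-D default)."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    if X is None:
        X = np.zeros((len(y), 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return [
        CensoredRecord(float(y[i]), int(delta[i]), CovariatePath.constant(X[i]))
        for i in range(len(y))
    ]


def random_censored(rng, n, ties=True, p=2):
    """Random censored data with possible tied times."""
    y = rng.integers(1, max(3, n // 2), n).astype(float) if ties else rng.exponential(2, n)
    delta = (rng.random(n) < 0.7).astype(int)
    X = rng.normal(size=(n, p))
    return make_records(y, delta, X), y, delta, X
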