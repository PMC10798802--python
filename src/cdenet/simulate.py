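"""Synthetic data generators with true-function oracles.

Three families of study designs are implemented:

* censored survival data with time-varying covariates — a scaled-Beta(8, 1)
  baseline hazard on [0, tau], a two-harmonic Fourier covariate path, a
  random-onset step covariate, three static covariates, and exponential
  censoring calibrated to a target censoring rate;
* uncensored mixture-error regressions — a fixed nonlinear mean function with
  either homoscedastic independent errors (setup 1) or heteroscedastic errors
  correlated with a covariate (setup 2);
* low-dimensional sine regressions with triangular noise, the classical
  kernel-smoothing test bed (1-D and 2-D).

Every generator takes an explicit seed / generator and is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .expansion import CensoredRecord

__all__ = [
    "CensoredSimConfig",
    "UncensoredSimConfig",
    "baseline_hazard",
    "gen_covariate_paths",
    "conditional_hazard",
    "draw_failure_times",
    "apply_censoring",
    "calibrate_censoring_rate",
    "gen_censored_records",
    "gen_uncensored",
    "mean_function",
    "true_cdf_uncensored",
    "gen_kernel_example",
    "true_cdf_kernel",
    "triangular_cdf",
    "triangular_ppf",
]

TAU_DEFAULT = 100.0
DELTA_S_DEFAULT = 0.01


@dataclass(frozen=True)
class CensoredSimConfig:
    n: int
    setup: str = "ph"                  # "ph" or "nonph"
    censor_rate_target: float = 0.20   # 0.20 (ph) / 0.50 (nonph) in the study design
    tau: float = TAU_DEFAULT
    delta_s: float = DELTA_S_DEFAULT
    seed: int | None = None

    def __post_init__(self):
        if self.tau <= 0 or not (0 < self.delta_s < self.tau):
            raise ValueError("need tau > 0 and 0 < delta_s << tau")
        if not 0 < self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must be in (0, 1)")
        if self.setup not in ("ph", "nonph"):
            raise ValueError(f"unknown setup {self.setup!r}")


@dataclass(frozen=True)
class UncensoredSimConfig:
    n: int
    setup: int = 1          # 1: independent constant-variance, 2: correlated heteroscedastic
    c: float = 0.5          # noise scale; larger c lowers the signal-to-noise ratio
    seed: int | None = None

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("noise scale c must be positive")
        if self.setup not in (1, 2):
            raise ValueError(f"unknown setup {self.setup!r}")


# ---------------------------------------------------------------------------
# censored design
# ---------------------------------------------------------------------------

def baseline_hazard(t, tau: float = TAU_DEFAULT):
    """Hazard of a Beta(8, 1) random variable scaled to [0, tau].

    With f0(u) = 8 u^7 and F0(u) = u^8 this is 8 (t/tau)^7 / (1 - (t/tau)^8);
    it vanishes at 0, increases strictly, and diverges at tau.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t >= tau):
        raise ValueError(f"baseline hazard requires 0 <= t < tau={tau}")
    u = t / tau
    return 8.0 * u**7 / (1.0 - u**8)


class SimCovariatePath:
    """Analytic covariate path (x1(t), x2(t), x3, x4, x5) of the censored design.

    x1 is a two-harmonic Fourier function with uniform random coefficients; x2
    steps from 0 to 1 strictly after the random onset q (left-continuous); the
    rest are static.  Duck-typed to :class:`~cdenet.expansion.CovariatePath`.
    """

    def __init__(self, alpha, q, static, tau):
        self.alpha = np.asarray(alpha, dtype=float)
        self.q = float(q)
        self.static = np.asarray(static, dtype=float)
        self.tau = float(tau)

    dimension = 5

    def x1(self, t):
        a = self.alpha
        w = 2 * np.pi * np.asarray(t, dtype=float) / self.tau
        return a[0] + a[1] * np.sin(w) + a[2] * np.cos(w) + a[3] * np.sin(2 * w) + a[4] * np.cos(2 * w)

    def x2(self, t):
        return (np.asarray(t, dtype=float) > self.q).astype(float)

    def __call__(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(t), 5))
        out[:, 0] = self.x1(t)
        out[:, 1] = self.x2(t)
        out[:, 2:] = self.static
        return out


@dataclass
class CovariateSample:
    """Vectorized covariate draws for n subjects of the censored design."""

    alpha: np.ndarray  # (n, 5) uniform(0,1) Fourier coefficients
    q: np.ndarray      # (n,) uniform(0, tau) step onsets
    x3: np.ndarray     # Bernoulli(0.6)
    x4: np.ndarray     # Poisson(2) truncated to {0..5} (resampled, not capped)
    x5: np.ndarray     # Beta(2, 5)
    tau: float

    @property
    def n(self) -> int:
        return len(self.q)

    def path(self, i: int) -> SimCovariatePath:
        return SimCovariatePath(
            self.alpha[i], self.q[i], (self.x3[i], self.x4[i], self.x5[i]), self.tau
        )

    def x1_at(self, t, idx=slice(None)):
        """x1 values, shape (subjects, len(t))."""
        t = np.asarray(t, dtype=float)
        w = 2 * np.pi * t / self.tau
        basis = np.stack(
            [np.ones_like(w), np.sin(w), np.cos(w), np.sin(2 * w), np.cos(2 * w)]
        )
        return self.alpha[idx] @ basis

    def x2_at(self, t, idx=slice(None)):
        t = np.asarray(t, dtype=float)
        return (t[None, :] > self.q[idx, None]).astype(float)


def _truncated_poisson(rng, lam, upper, size):
    out = rng.poisson(lam, size)
    bad = out > upper
    while bad.any():
        out[bad] = rng.poisson(lam, bad.sum())
        bad = out > upper
    return out


def _truncated_normal(rng, loc, scale, bound, size):
    out = rng.normal(loc, scale, size)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = np.abs(out) > bound
    return out


def gen_covariate_paths(n, tau=TAU_DEFAULT, delta_s=DELTA_S_DEFAULT, seed=None) -> CovariateSample:
    """Draw the covariate structure of the censored design for n subjects."""
    rng = np.random.default_rng(seed)
    return CovariateSample(
        alpha=rng.uniform(0.0, 1.0, (n, 5)),
        q=rng.uniform(0.0, tau, n),
        x3=(rng.random(n) < 0.6).astype(float),
        x4=_truncated_poisson(rng, 2.0, 5, n).astype(float),
        x5=rng.beta(2.0, 5.0, n),
        tau=tau,
    )


def conditional_hazard(t, x1, x2, x3, x4, x5, setup: str, tau: float = TAU_DEFAULT):
    """Conditional hazard of the two censored designs.

    ``ph``    : lambda0(t) exp(2 x1(t) + 2 x2(t) + 2 x3 + 2 x4 + 2 x5)
    ``nonph`` : lambda0(t) exp(2 x1(t)^2 + 2 x2(t) + 2 x3 x4 + 2 x5)
    """
    lam0 = baseline_hazard(t, tau)
    if setup == "ph":
        eta = 2 * x1 + 2 * x2 + 2 * x3 + 2 * x4 + 2 * x5
    elif setup == "nonph":
        eta = 2 * x1**2 + 2 * x2 + 2 * x3 * x4 + 2 * x5
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return lam0 * np.exp(eta)


def _hazard_on_grid(cov: CovariateSample, setup, grid, idx, hazard_override=None):
    """(subjects, len(grid)) hazard matrix on the fine grid."""
    if hazard_override is not None:
        n_sub = len(cov.q[idx]) if not isinstance(idx, slice) else cov.n
        return np.broadcast_to(
            np.asarray(hazard_override(grid), dtype=float), (n_sub, len(grid))
        )
    x1 = cov.x1_at(grid, idx)
    x2 = cov.x2_at(grid, idx)
    return conditional_hazard(
        grid[None, :], x1, x2,
        cov.x3[idx, None], cov.x4[idx, None], cov.x5[idx, None],
        setup, cov.tau,
    )


def draw_failure_times(
    cov: CovariateSample,
    setup: str,
    delta_s: float = DELTA_S_DEFAULT,
    seed=None,
    hazard_override=None,
    chunk: int = 256,
):
    """Inverse-transform failure times on the fine grid.

    Per subject the survival curve is S(t) = exp(-delta_s * sum_{s<=t} lambda(s))
    on {0, delta_s, ..., tau - delta_s}; with u ~ Uniform(0,1) the failure
    time is the largest grid point where S >= u, and subjects still surviving
    at the end of the grid are administratively capped at tau (later treated
    as censored there).  ``hazard_override`` replaces the design hazard with
    an arbitrary function of time, which is convenient for distributional
    checks against closed forms.
    """
    rng = np.random.default_rng(seed)
    tau = cov.tau
    grid = np.arange(0.0, tau - delta_s / 2, delta_s)
    u = rng.uniform(0.0, 1.0, cov.n)
    T = np.empty(cov.n)
    for lo in range(0, cov.n, chunk):
        idx = np.arange(lo, min(lo + chunk, cov.n))
        lam = _hazard_on_grid(cov, setup, grid, idx, hazard_override)
        S = np.exp(-delta_s * np.cumsum(lam, axis=1))
        # S is non-increasing; count grid points with S >= u
        k = (S >= u[idx, None]).sum(axis=1)
        T[idx] = np.where(k >= len(grid), tau, grid[np.minimum(k, len(grid) - 1)])
        # k==0 -> S(0) < u: failure at the first grid point (time 0)
        T[idx] = np.where(k == 0, grid[0], T[idx])
    return T


def apply_censoring(failure_times, rate, tau=TAU_DEFAULT, seed=None):
    """Exponential censoring C ~ Exp(rate): y = min(T, C), delta = 1(T <= C).

    Administratively capped failure times (T == tau) count as censored at tau.
    """
    if rate <= 0:
        raise ValueError("censoring rate parameter must be positive")
    rng = np.random.default_rng(seed)
    T = np.asarray(failure_times, dtype=float)
    C = rng.exponential(1.0 / rate, len(T))
    y = np.minimum(np.minimum(T, C), tau)
    delta = ((T <= C) & (T < tau)).astype(int)
    return y, delta


def calibrate_censoring_rate(
    setup: str,
    target: float,
    seed=None,
    m: int = 20000,
    tau: float = TAU_DEFAULT,
    delta_s: float = DELTA_S_DEFAULT,
):
    """Exponential rate whose expected censoring fraction matches ``target``.

    A pilot sample of m failure times is drawn once; conditionally on a
    failure time T < tau, the probability of being censored by C ~ Exp(r) is
    1 - exp(-r T) exactly, so the expected censoring fraction is a smooth
    monotone function of r and the root is found by bracketing.
    """
    if not 0 < target < 1:
        raise ValueError("target censoring rate must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    s_cov, s_fail = ss.spawn(2)
    cov = gen_covariate_paths(m, tau, delta_s, seed=s_cov)
    T = draw_failure_times(cov, setup, delta_s, seed=s_fail)
    capped = T >= tau

    def frac(r):
        p = np.where(capped, 1.0, -np.expm1(-r * T))
        return p.mean() - target

    lo, hi = 1e-8, 1.0
    if frac(lo) > 0:
        raise ValueError(
            f"target {target} below the administrative-censoring floor {frac(lo) + target:.4f}"
        )
    while frac(hi) < 0:
        hi *= 10
        if hi > 1e6:
            raise ValueError("could not bracket the censoring rate")
    return float(brentq(frac, lo, hi, xtol=1e-10))


def gen_censored_records(config: CensoredSimConfig, rate: float | None = None):
    """Full censored data set: list of records plus the generating truth.

    Returns (records, info) where info carries the covariate sample, the
    latent failure times and the censoring rate actually used (calibrated to
    the configured target when ``rate`` is not given).
    """
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_fail, s_cens, s_cal = ss.spawn(4)
    if rate is None:
        rate = calibrate_censoring_rate(
            config.setup, config.censor_rate_target, seed=s_cal,
            tau=config.tau, delta_s=config.delta_s,
        )
    cov = gen_covariate_paths(config.n, config.tau, config.delta_s, seed=s_cov)
    T = draw_failure_times(cov, config.setup, config.delta_s, seed=s_fail)
    y, delta = apply_censoring(T, rate, config.tau, seed=s_cens)
    records = [
        CensoredRecord(float(y[i]), int(delta[i]), cov.path(i))
        for i in range(config.n)
    ]
    info = {"cov": cov, "failure_times": T, "rate": rate}
    return records, info


def true_survival_censored(cov: CovariateSample, i: int, times, setup: str,
                           delta_s: float = DELTA_S_DEFAULT):
    """True S(t | path_i) at the requested times (fine-grid Riemann sum)."""
    tau = cov.tau
    grid = np.arange(0.0, tau - delta_s / 2, delta_s)
    lam = _hazard_on_grid(cov, setup, grid, np.array([i]))[0]
    cum = delta_s * np.cumsum(lam)
    S_grid = np.exp(-cum)
    k = np.searchsorted(grid, np.asarray(times, dtype=float), side="right")
    S = np.concatenate([[1.0], S_grid])
    return S[k]


# ---------------------------------------------------------------------------
# uncensored mixture-error design
# ---------------------------------------------------------------------------

def mean_function(X):
    """m(x) = x1^2 + x2 x3 + x3 x4 + x5."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X[:, 0] ** 2 + X[:, 1] * X[:, 2] + X[:, 2] * X[:, 3] + X[:, 4]


def _draw_eps(rng, x6):
    """Mixture error: N(-2,1) w.p. 0.1, N(0,1) w.p. 0.7, 0.5 x6^2 w.p. 0.2."""
    m = len(x6)
    comp = rng.choice(3, size=m, p=(0.1, 0.7, 0.2))
    eps = np.empty(m)
    eps[comp == 0] = rng.normal(-2.0, 1.0, (comp == 0).sum())
    eps[comp == 1] = rng.normal(0.0, 1.0, (comp == 1).sum())
    eps[comp == 2] = 0.5 * x6[comp == 2] ** 2
    return eps


def gen_uncensored(config: UncensoredSimConfig):
    """Mixture-error regression draw.

    Returns (X, y, info): X holds the five observed covariates (the error-
    building covariate x6 is latent and never exposed as a predictor), y the
    responses; info carries x6, the raw errors and the noise scale g(x).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    X = np.column_stack(
        [
            _truncated_normal(rng, 0.0, 1.0, 3.0, n),
            rng.uniform(0.0, 1.0, n),
            rng.beta(0.5, 0.5, n),
            (rng.random(n) < 0.5).astype(float),
            _truncated_poisson(rng, 2.0, 5, n).astype(float),
        ]
    )
    if config.setup == 1:
        x6 = rng.normal(1.0, 1.0, n)
        g = np.full(n, config.c)
    else:
        x6 = rng.normal(1.0 + 0.5 * X[:, 0], np.sqrt(0.75), n)
        g = config.c * X[:, 0] ** 2
    eps = _draw_eps(rng, x6)
    y = mean_function(X) + eps * g
    return X, y, {"x6": x6, "eps": eps, "g": g}


def true_cdf_uncensored(x, ys, setup: int, c: float, n_mc: int = 100_000,
                        seed: int = 202304):
    """Monte-Carlo oracle for F(y | x1..x5) of the mixture-error design.

    Setup 2 requires integrating over x6 | x1 inside the 0.5 x6^2 mixture
    component; a fixed-seed Monte-Carlo sample (accuracy ~1/sqrt(n_mc)) keeps
    the oracle simple and testable.
    """
    x = np.asarray(x, dtype=float).ravel()
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    rng = np.random.default_rng(seed)
    if setup == 1:
        x6 = rng.normal(1.0, 1.0, n_mc)
        g = c
    elif setup == 2:
        x6 = rng.normal(1.0 + 0.5 * x[0], np.sqrt(0.75), n_mc)
        g = c * x[0] ** 2
    else:
        raise ValueError(f"unknown setup {setup!r}")
    eps = _draw_eps(rng, x6)
    draws = mean_function(x[None, :])[0] + eps * g
    return np.searchsorted(np.sort(draws), ys, side="right") / n_mc


# ---------------------------------------------------------------------------
# triangular-noise sine designs (kernel test bed)
# ---------------------------------------------------------------------------

PI_SINE = 3.1416  # the design uses this 4-decimal constant, not numpy pi


def triangular_cdf(x):
    """CDF of the density 1 - |x| on [-1, 1] (0 below, 1 above the support)."""
    x = np.clip(np.asarray(x, dtype=float), -1.0, 1.0)
    return np.where(x < 0, 0.5 * (1.0 + x) ** 2, 1.0 - 0.5 * (1.0 - x) ** 2)


def triangular_ppf(u):
    """Inverse of :func:`triangular_cdf` on (0, 1)."""
    u = np.asarray(u, dtype=float)
    return np.where(u < 0.5, -1.0 + np.sqrt(2.0 * u), 1.0 - np.sqrt(2.0 * (1.0 - u)))


def _kernel_mean(X, dims):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = 2.0 * np.sin(PI_SINE * X[:, 0])
    if dims == 2:
        m = m + X[:, 1]
    return m


def gen_kernel_example(n: int, dims: int = 1, seed=None):
    """Sine regression with triangular covariate and noise.

    1-D: Y = 2 sin(pi X) + eps, X and eps both triangular on [-1, 1];
    2-D adds an independent Uniform(-1, 1) covariate to the mean.
    """
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    rng = np.random.default_rng(seed)
    X1 = triangular_ppf(rng.uniform(0.0, 1.0, n))
    if dims == 1:
        X = X1[:, None]
    else:
        X = np.column_stack([X1, rng.uniform(-1.0, 1.0, n)])
    eps = triangular_ppf(rng.uniform(0.0, 1.0, n))
    y = _kernel_mean(X, dims) + eps
    return X, y


def true_cdf_kernel(x, ys, dims: int = 1):
    """Closed-form F(y | x): the triangular CDF shifted by the mean function."""
    m = _kernel_mean(np.asarray(x, dtype=float)[None, :], dims)[0]
    return triangular_cdf(np.asarray(ys, dtype=float) - m)
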