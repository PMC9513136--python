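"""Hyperbolic discounting + softmax choice model and its ML estimator.

The subjective value of a reward V delivered after D days is
``SV = V / (1 + k*D)`` with per-day discount rate k in (0, 1). Choices
between the immediate and delayed option follow a softmax on the SV
difference with inverse temperature mu (units 1/KRW, since SVs are in
KRW):

    P(immediate) = 1 / (1 + exp(-mu * (SV_immediate - SV_delayed)))

Per participant-session, (k, mu) is estimated by maximising the summed
log probability of the observed choices with a multi-start Nelder-Mead
search in a transformed space (k through a logistic map, mu through log)
so both constraints hold automatically. All reported log k use base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from itclab.staircase import TrialRecord

# Boundary tolerances used to flag unidentifiable discount rates: an
# estimate pinned this close to the (0, 1) bounds carries no information.
K_LOWER_BOUNDARY = 1e-4
K_UPPER_BOUNDARY = 0.99


@dataclass(frozen=True)
class DiscountParams:
    """Hyperbolic discount rate k (per day) and softmax inverse temperature mu."""

    k: float
    mu: float

    def __post_init__(self) -> None:
        if not (0.0 < self.k < 1.0) or not math.isfinite(self.k):
            raise ValueError(f"k must lie strictly in (0, 1); got {self.k}")
        if self.mu < 0 or not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite and >= 0; got {self.mu}")

    @property
    def log10_k(self) -> float:
        return math.log10(self.k)


@dataclass(frozen=True)
class FitResult:
    params: DiscountParams
    log_likelihood: float
    n_starts: int
    converged: bool
    unique: bool
    start_optima: tuple[tuple[DiscountParams, float], ...]

    @property
    def log10_k(self) -> float:
        return self.params.log10_k

    @property
    def nll(self) -> float:
        return -self.log_likelihood


def subjective_value(V, D, k):
    """Hyperbolic subjective value V / (1 + k*D). Accepts arrays for V, D."""
    V = np.asarray(V, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(V <= 0):
        raise ValueError("reward V must be positive")
    if np.any(D < 0):
        raise ValueError("delay D must be non-negative")
    if not (0.0 < k < 1.0):
        raise ValueError(f"discount rate k must lie in (0, 1); got {k}")
    out = V / (1.0 + k * D)
    return float(out) if out.ndim == 0 else out


def p_immediate(sv_immediate, sv_delayed, mu: float):
    """Softmax probability of choosing the immediate option.

    Numerically stable for any SV difference; mu = 0 gives 0.5.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    dv = mu * (np.asarray(sv_immediate, dtype=float) - np.asarray(sv_delayed, dtype=float))
    out = expit(dv)
    return float(out) if out.ndim == 0 else out


def _trial_arrays(trials: Sequence[TrialRecord]):
    delayed = np.array([t.delayed_reward for t in trials], dtype=float)
    delays = np.array([t.delay_days for t in trials], dtype=float)
    immediate = np.array([t.immediate_reward for t in trials], dtype=float)
    # sign +1 where the immediate option was chosen
    sign = np.array([1.0 if t.choice == "immediate" else -1.0 for t in trials])
    return immediate, delayed, delays, sign


def _nll_from_arrays(k: float, mu: float, immediate, delayed, delays, sign) -> float:
    sv_del = delayed / (1.0 + k * delays)
    dv = mu * (immediate - sv_del)
    # log P(chosen) = -log(1 + exp(-sign*dv)), stable via logaddexp
    return float(np.sum(np.logaddexp(0.0, -sign * dv)))


def negative_log_likelihood(params: DiscountParams,
                            trials: Sequence[TrialRecord]) -> float:
    """-sum_i log P(choice_i | k, mu), natural log; order-invariant."""
    if len(trials) == 0:
        raise ValueError("trial list is empty")
    return _nll_from_arrays(params.k, params.mu, *_trial_arrays(trials))


def _start_grid(n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified (Latin) starting points over log10 k x log10 mu.

    Levels span log10 k in [-4, -0.5] and log10 mu in [-5, -2]; each axis
    is divided into n_starts strata, paired by a seeded shuffle with
    within-stratum jitter.
    """
    lk = np.linspace(-4.0, -0.5, n_starts, endpoint=True)
    lm = np.linspace(-5.0, -2.0, n_starts, endpoint=True)
    if n_starts > 1:
        jk = (3.5 / (n_starts - 1)) * 0.3
        jm = (3.0 / (n_starts - 1)) * 0.3
        lk = lk + rng.uniform(-jk, jk, n_starts)
        lm = rng.permutation(lm + rng.uniform(-jm, jm, n_starts))
    return np.column_stack([lk, lm])


def fit_mle(trials: Sequence[TrialRecord], n_starts: int = 10,
            seed: int | np.random.Generator | None = 0) -> FitResult:
    """Maximum-likelihood fit of (k, mu) for one participant-session.

    Runs Nelder-Mead from ``n_starts`` stratified starting points in the
    transformed space (logit k, log mu); returns the best optimum, ties
    broken toward the smaller k. Sessions where every choice is the same
    option are fitted but flagged ``unique=False`` (k is pinned at a
    boundary and carries no information).
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to fit")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    immediate, delayed, delays, sign = _trial_arrays(trials)
    if np.unique(np.column_stack([delayed, delays]), axis=0).shape[0] == 1:
        raise ValueError("degenerate input: all trials present the identical offer")
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        k = expit(x[0])
        mu = math.exp(x[1])
        if k <= 0.0 or k >= 1.0 or not math.isfinite(mu):
            return 1e12
        return _nll_from_arrays(k, mu, immediate, delayed, delays, sign)

    optima: list[tuple[DiscountParams, float]] = []
    any_converged = False
    for lk0, lm0 in _start_grid(n_starts, rng):
        x0 = np.array([logit(10.0 ** lk0), math.log(10.0 ** lm0)])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600})
        k_hat = float(np.clip(expit(res.x[0]), 1e-12, 1 - 1e-12))
        mu_hat = float(math.exp(res.x[1]))
        optima.append((DiscountParams(k=k_hat, mu=mu_hat), -float(res.fun)))
        any_converged = any_converged or bool(res.success)

    # best log-likelihood; ties (within strict equality) broken by lowest k
    best = max(optima, key=lambda o: (o[1], -o[0].k))
    one_sided = abs(np.mean(sign)) == 1.0
    fit = FitResult(
        params=best[0],
        log_likelihood=best[1],
        n_starts=n_starts,
        converged=any_converged,
        unique=True,
        start_optima=tuple(optima),
    )
    unique = (not one_sided) and check_unique_solution(fit)
    return FitResult(
        params=fit.params,
        log_likelihood=fit.log_likelihood,
        n_starts=fit.n_starts,
        converged=fit.converged,
        unique=unique,
        start_optima=fit.start_optima,
    )


def check_unique_solution(fit: FitResult, nll_tol: float = 0.01,
                          param_tol: float = 0.1) -> bool:
    """Did the multi-start search identify a single interior optimum?

    Returns False when (a) another start converged to a likelihood within
    ``nll_tol`` of the best but with |delta log10 k| > ``param_tol`` (a
    flat ridge), or (b) the best k sits at the (0, 1) boundary.
    """
    k_best = fit.params.k
    if k_best <= K_LOWER_BOUNDARY or k_best >= K_UPPER_BOUNDARY:
        return False
    nll_best = fit.nll
    lk_best = fit.params.log10_k
    for params, ll in fit.start_optima:
        if abs(-ll - nll_best) <= nll_tol and abs(params.log10_k - lk_best) > param_tol:
            return False
    return True
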