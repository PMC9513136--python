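"""Synthetic intervention-study cohorts with known ground truth.

Each simulated participant owns hyperbolic-discounting parameters
(log10 k, log10 mu) drawn from population distributions, completes a
closed-loop 180-trial staircase ITC session before and after an
"intervention", and produces a Serial-7s accuracy trace whose per-trial
success probability follows a saturating learning curve

    p(t) = p0 + (p1 - p0) * (1 - exp(-rate * t)).

An intervention is an additive shift of log10 k between sessions
(positive ``delta_log10_k`` reduces the post-session discount rate,
i.e. reduces impulsivity), plus idiosyncratic test-retest jitter. A
Gaussian copula with correlation ``slope_effect_corr`` couples each
participant's learning rate with their individual pre-to-post shift, so
cohorts can emulate either a null or a "faster learners improve more"
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from itclab.model import DiscountParams, p_immediate, subjective_value
from itclab.staircase import (
    Phase,
    StaircaseConfig,
    TrialOffer,
    TrialRecord,
    generate_session,
)


def softmax_policy(params: DiscountParams):
    """Stochastic agent: choice sampled from the softmax choice rule."""

    def policy(offer: TrialOffer, rng: np.random.Generator):
        sv_del = subjective_value(offer.delayed_reward, offer.delay_days, params.k)
        p = p_immediate(offer.immediate_reward, sv_del, params.mu)
        return "immediate" if rng.random() < p else "delayed"

    return policy


def threshold_policy(params: DiscountParams):
    """Deterministic (mu -> infinity) agent: delayed iff SV_delayed > SV_immediate."""

    def policy(offer: TrialOffer, rng: np.random.Generator):
        sv_del = subjective_value(offer.delayed_reward, offer.delay_days, params.k)
        return "delayed" if sv_del > offer.immediate_reward else "immediate"

    return policy


def simulate_agent_session(
    params: DiscountParams,
    phase: Phase = "pre",
    config: StaircaseConfig | None = None,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
) -> list[TrialRecord]:
    """One closed-loop staircase session of a softmax agent (180 trials)."""
    return generate_session(softmax_policy(params), config=config, rng=seed,
                            participant_id=participant_id, phase=phase)


@dataclass(frozen=True)
class GroupSpec:
    """One intervention arm: label, size, and true effect on log10 k."""

    label: str
    n: int
    delta_log10_k: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r} must have n >= 1")


@dataclass(frozen=True)
class WMLearning:
    """Serial-7s learning curve: accuracy p0 -> p1 at exponential rate/trial."""

    p0: float = 0.5
    p1: float = 0.9
    rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p0", "p1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    def curve(self, n_trials: int) -> np.ndarray:
        t = np.arange(n_trials, dtype=float)
        return self.p0 + (self.p1 - self.p0) * (1.0 - np.exp(-self.rate * t))


@dataclass(frozen=True)
class CohortDesign:
    """Population and design parameters of a synthetic study.

    Defaults mirror the study structure: baseline log10 k ~ N(-2, 0.5),
    log10 mu ~ N(-3.5, 0.3), two 180-trial staircase sessions per
    participant, 240 Serial-7s trials with a 0.5 -> 0.9 learning curve.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("working-memory", 30, 0.0),
        GroupSpec("control-wm", 30, 0.0),
        GroupSpec("rest", 30, 0.0),
    )
    log10_k_mean: float = -2.0
    log10_k_sd: float = 0.5
    log10_mu_mean: float = -3.5
    log10_mu_sd: float = 0.3
    wm_learning: WMLearning = field(default_factory=WMLearning)
    wm_trials: int = 240
    rate_log_sd: float = 0.3
    test_retest_sd: float = 0.1
    slope_effect_corr: float = 0.0
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        if self.log10_k_sd < 0 or self.log10_mu_sd < 0 or self.test_retest_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (-1.0 <= self.slope_effect_corr <= 1.0):
            raise ValueError("slope_effect_corr must lie in [-1, 1]")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


def experiment1_design(n_per_group: int = 23, seed: int = 0,
                       wm_effect: float = 0.0,
                       slope_effect_corr: float = 0.5) -> CohortDesign:
    """Five-arm design emulating the first experiment's structure.

    The positive ``slope_effect_corr`` preset reproduces the scenario in
    which faster working-memory learners show larger impulsivity
    reductions.
    """
    labels = ("associative-memory", "control-am", "working-memory",
              "control-wm", "rest")
    effects = {"working-memory": wm_effect}
    return CohortDesign(
        groups=tuple(GroupSpec(lb, n_per_group, effects.get(lb, 0.0))
                     for lb in labels),
        slope_effect_corr=slope_effect_corr,
        seed=seed,
    )


def experiment2_design(n_per_group: int = 25, seed: int = 0) -> CohortDesign:
    """Three-arm replication design (all-null effects, zero copula)."""
    return CohortDesign(
        groups=(GroupSpec("working-memory", n_per_group),
                GroupSpec("control-wm", n_per_group),
                GroupSpec("rest", n_per_group)),
        slope_effect_corr=0.0,
        seed=seed,
    )


@dataclass
class Cohort:
    """A fully simulated study with its generating ground truth."""

    design: CohortDesign
    trials: list[TrialRecord]
    traces: dict[str, np.ndarray]
    truth: pd.DataFrame

    def session(self, participant_id: str, phase: Phase) -> list[TrialRecord]:
        return [t for t in self.trials
                if t.participant_id == participant_id and t.phase == phase]


def _clip_log10_k(lk: np.ndarray) -> np.ndarray:
    # keep k strictly inside (0, 1); the upper clip only binds in the
    # extreme tail of the population distribution
    return np.clip(lk, -6.0, -0.05)


def simulate_cohort(design: CohortDesign) -> Cohort:
    """Simulate every participant of ``design`` end to end.

    Per participant: draw baseline (log10 k, log10 mu); run the pre
    staircase session; shift log10 k by the group effect plus test-retest
    jitter; run the post session; draw the Serial-7s accuracy trace from
    the participant's learning curve. All generating values are retained
    in ``truth``.
    """
    rng = np.random.default_rng(design.seed)
    rho = design.slope_effect_corr
    trials: list[TrialRecord] = []
    traces: dict[str, np.ndarray] = {}
    rows = []
    for group in design.groups:
        for i in range(group.n):
            pid = f"{group.label}-{i:03d}"
            lk_pre = float(_clip_log10_k(
                rng.normal(design.log10_k_mean, design.log10_k_sd)))
            lmu = float(rng.normal(design.log10_mu_mean, design.log10_mu_sd))
            # Gaussian copula: z1 drives the learning rate, z2 the
            # idiosyncratic component of the pre-to-post shift
            z1 = rng.standard_normal()
            z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal()
            rate_i = design.wm_learning.rate * float(np.exp(design.rate_log_sd * z1))
            shift = group.delta_log10_k + design.test_retest_sd * z2
            lk_post = float(_clip_log10_k(np.asarray(lk_pre - shift)))

            pre_params = DiscountParams(k=10.0 ** lk_pre, mu=10.0 ** lmu)
            post_params = DiscountParams(k=10.0 ** lk_post, mu=10.0 ** lmu)
            trials += simulate_agent_session(pre_params, "pre", design.staircase,
                                             rng, participant_id=pid)
            trials += simulate_agent_session(post_params, "post", design.staircase,
                                             rng, participant_id=pid)

            curve = WMLearning(design.wm_learning.p0, design.wm_learning.p1,
                               rate_i).curve(design.wm_trials)
            traces[pid] = (rng.random(design.wm_trials) < curve).astype(int)
            rows.append({
                "participant_id": pid,
                "group": group.label,
                "log10_k_pre": lk_pre,
                "log10_k_post": lk_post,
                "log10_mu": lmu,
                "delta_log10_k_true": lk_pre - lk_post,
                "group_effect": group.delta_log10_k,
                "wm_rate": rate_i,
            })
    return Cohort(design=design, trials=trials, traces=traces,
                  truth=pd.DataFrame(rows))
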