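"""Adaptive staircase engine for the intertemporal-choice (ITC) task.

Every trial offers a fixed immediate reward of 10,000 KRW against a larger
delayed reward. The delayed option is parameterised by one of six delays
(1, 10, 21, 50, 90, 180 days) and one of two initial amounts (15,000 or
20,000 KRW); each (delay, initial value) pair runs its own five-step
staircase ("arm") that titrates the delayed amount toward the agent's
indifference point. A block presents the 12 arms interleaved in random
order (60 trials); a session is three blocks, 180 trials.

Two titration schedules are provided (``StaircaseConfig.exponent_mode``):

``halving``
    The step taken after answering the t-th offer is 10,000 x (1/2)^t
    (so the first adjustment is +/-5,000), and a delayed choice on a
    15,000-arm halves the gap to the immediate reward:
    next = 10,000 + (current - 10,000)/2. With floor-to-100 rounding this
    schedule spans offered rewards 10,300-29,300 KRW, a proper bisection.

``literal``
    The step after the t-th offer is 10,000 x (1/2)^(t-1) (first
    adjustment +/-10,000); the 15,000-arm exception uses the factor
    (1/2)^(t-1) on the gap, so a first delayed choice lands exactly on
    10,000 KRW.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

IMMEDIATE_REWARD = 10_000
DELAYS: tuple[int, ...] = (1, 10, 21, 50, 90, 180)
INITIAL_VALUES: tuple[int, ...] = (15_000, 20_000)
STEPS_PER_ARM = 5
BLOCKS_PER_SESSION = 3
TRIALS_PER_BLOCK = len(DELAYS) * len(INITIAL_VALUES) * STEPS_PER_ARM
TRIALS_PER_SESSION = BLOCKS_PER_SESSION * TRIALS_PER_BLOCK

Choice = Literal["immediate", "delayed"]
Phase = Literal["pre", "post"]


class ExhaustedBlockError(RuntimeError):
    """All 12 arms have presented their five offers."""


class ExhaustedArmError(RuntimeError):
    """The arm has already answered its fifth (final) offer."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Titration settings.

    Parameters
    ----------
    exponent_mode:
        ``"halving"`` (default) or ``"literal"``; see the module docstring.
    floor100:
        Round each new delayed reward down to the nearest 100 KRW.
    min_margin:
        Lower clamp: the delayed reward is never set below
        ``10,000 + min_margin`` KRW. The default 0 permits equality with
        the immediate reward (only reachable under ``literal``).
    """

    exponent_mode: Literal["halving", "literal"] = "halving"
    floor100: bool = True
    min_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.exponent_mode not in ("halving", "literal"):
            raise ValueError(f"unknown exponent_mode {self.exponent_mode!r}")
        if self.min_margin < 0:
            raise ValueError("min_margin must be >= 0")


@dataclass(frozen=True)
class StaircaseArm:
    """State of one (delay, initial value) staircase within a block."""

    delay_days: int
    initial_value: int
    current_delayed_reward: float
    offer_history: tuple[tuple[float, Choice], ...] = ()

    @property
    def step(self) -> int:
        """1-based index of the next offer (1..5)."""
        return len(self.offer_history) + 1

    @property
    def exhausted(self) -> bool:
        return len(self.offer_history) >= STEPS_PER_ARM

    @property
    def arm_id(self) -> tuple[int, int]:
        return (self.delay_days, self.initial_value)


@dataclass(frozen=True)
class TrialOffer:
    immediate_reward: float
    delayed_reward: float
    delay_days: int
    arm_id: tuple[int, int]
    step: int
    block: int


@dataclass(frozen=True)
class TrialRecord:
    """One answered ITC trial, with provenance."""

    participant_id: str
    phase: Phase
    block: int
    trial_index: int
    delay_days: int
    immediate_reward: float
    delayed_reward: float
    arm_id: tuple[int, int]
    step: int
    choice: Choice


def init_block() -> list[StaircaseArm]:
    """Create the 12 fresh staircase arms (6 delays x 2 initial values)."""
    return [
        StaircaseArm(delay_days=d, initial_value=v, current_delayed_reward=float(v))
        for d in DELAYS
        for v in INITIAL_VALUES
    ]


def next_offer(
    arms: Sequence[StaircaseArm],
    rng: np.random.Generator,
    block: int = 1,
) -> TrialOffer:
    """Draw the next trial uniformly among arms with remaining steps.

    The arm presented on the previous trial stays in the candidate set, so
    immediate repetitions can occur.
    """
    active = [a for a in arms if not a.exhausted]
    if not active:
        raise ExhaustedBlockError("all 12 arms have completed their 5 steps")
    arm = active[rng.integers(len(active))]
    return TrialOffer(
        immediate_reward=float(IMMEDIATE_REWARD),
        delayed_reward=arm.current_delayed_reward,
        delay_days=arm.delay_days,
        arm_id=arm.arm_id,
        step=arm.step,
        block=block,
    )


def _floor100(x: float) -> float:
    # tiny epsilon guards binary-fraction values sitting just below a boundary
    return math.floor(x / 100.0 + 1e-9) * 100.0


def _next_reward(current: float, t: int, choice: Choice, initial_value: int,
                 config: StaircaseConfig) -> float:
    """Delayed reward for step t+1 after answering the t-th offer."""
    if config.exponent_mode == "halving":
        step_size = IMMEDIATE_REWARD * 0.5 ** t
        if choice == "immediate":
            nxt = current + step_size
        elif initial_value == 15_000:
            nxt = IMMEDIATE_REWARD + (current - IMMEDIATE_REWARD) * 0.5
        else:
            nxt = current - step_size
    else:  # literal
        factor = 0.5 ** (t - 1)
        if choice == "immediate":
            nxt = current + IMMEDIATE_REWARD * factor
        elif initial_value == 15_000:
            nxt = current - (current - IMMEDIATE_REWARD) * factor
        else:
            nxt = current - IMMEDIATE_REWARD * factor
    if config.floor100:
        nxt = _floor100(nxt)
    return max(nxt, IMMEDIATE_REWARD + config.min_margin)


def update_arm(arm: StaircaseArm, choice: Choice,
               config: StaircaseConfig | None = None) -> StaircaseArm:
    """Record the answer to the arm's current offer and titrate the reward.

    Returns a new arm with the answer appended; after the fifth answer the
    arm is exhausted and the reward is left at its final offered value.
    """
    if config is None:
        config = StaircaseConfig()
    if arm.exhausted:
        raise ExhaustedArmError(
            f"arm {arm.arm_id} already answered its {STEPS_PER_ARM} offers")
    if choice not in ("immediate", "delayed"):
        raise ValueError(f"unknown choice {choice!r}")
    t = arm.step
    history = arm.offer_history + ((arm.current_delayed_reward, choice),)
    if t < STEPS_PER_ARM:
        nxt = _next_reward(arm.current_delayed_reward, t, choice,
                           arm.initial_value, config)
    else:
        nxt = arm.current_delayed_reward
    return replace(arm, current_delayed_reward=nxt, offer_history=history)


def generate_session(
    policy: Callable[[TrialOffer, np.random.Generator], Choice],
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
    participant_id: str = "sim",
    phase: Phase = "pre",
) -> list[TrialRecord]:
    """Run one closed-loop 180-trial session (3 blocks x 60 trials).

    ``policy`` maps a :class:`TrialOffer` to a choice; it may consume the
    random stream (stochastic agents).
    """
    if config is None:
        config = StaircaseConfig()
    rng = np.random.default_rng(rng)
    records: list[TrialRecord] = []
    trial_index = 0
    for block in range(1, BLOCKS_PER_SESSION + 1):
        arms = {a.arm_id: a for a in init_block()}
        for _ in range(TRIALS_PER_BLOCK):
            offer = next_offer(list(arms.values()), rng, block=block)
            choice = policy(offer, rng)
            trial_index += 1
            records.append(TrialRecord(
                participant_id=participant_id,
                phase=phase,
                block=block,
                trial_index=trial_index,
                delay_days=offer.delay_days,
                immediate_reward=offer.immediate_reward,
                delayed_reward=offer.delayed_reward,
                arm_id=offer.arm_id,
                step=offer.step,
                choice=choice,
            ))
            arms[offer.arm_id] = update_arm(arms[offer.arm_id], choice, config)
    return records


def enumerate_offer_paths(
    arm: StaircaseArm, config: StaircaseConfig | None = None
) -> list[tuple[tuple[Choice, ...], tuple[float, ...]]]:
    """Exhaustively enumerate the 2^4 choice paths of a fresh arm.

    Returns, for every sequence of answers to the first four offers, the
    five delayed rewards the arm offers along that path. (The answer to
    the fifth offer cannot influence any offer, so 16 paths suffice.)
    """
    if config is None:
        config = StaircaseConfig()
    out = []
    for choices in itertools.product(("immediate", "delayed"), repeat=STEPS_PER_ARM - 1):
        a = arm
        offers = [a.current_delayed_reward]
        for c in choices:
            a = update_arm(a, c, config)
            offers.append(a.current_delayed_reward)
        out.append((choices, tuple(offers)))
    return out


def offered_reward_range(config: StaircaseConfig | None = None) -> tuple[float, float]:
    """(min, max) delayed reward offered over all arms and choice paths."""
    lo, hi = math.inf, -math.inf
    for arm in init_block():
        for _, offers in enumerate_offer_paths(arm, config):
            lo = min(lo, min(offers))
            hi = max(hi, max(offers))
    return lo, hi
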