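"""Logic of the cognitive intervention tasks.

Four scorable tasks sit between the two ITC sessions of an intervention
study:

* **Associative memory (AM)** — participants memorise 30 country ->
  "trip preparation time" pairs; six of the delays are the target delays
  also used in the ITC task (1, 10, 21, 50, 90, 180 days). Encoding shows
  every pair twice (60 trials); retrieval cues each target delay three
  times and each non-target once (42 trials).
* **Control_AM** — identical schedule, but delays are replaced by office
  supply items whose (annotated) word length matches the digit count of
  the replaced delay, so nothing in the ITC task can cue retrieval.
* **Serial 7s working memory (WM)** — repeatedly subtract 7 from the
  previous answer; the task resets with a new random number in
  [107, 999] on a wrong answer, on a timeout, or when the next expected
  answer would drop below 100.
* **Control_WM spatial attention** — press the arrow key matching the
  stimulus side within 1.5 s.

The country and office-supply lexicons bundled here are synthetic
stand-ins: only the six printed anchor pairs (Japan-1 day ... Brazil-180
days) and the structural contracts (counts, distinctness, length
matching) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

TARGET_DELAYS: tuple[int, ...] = (1, 10, 21, 50, 90, 180)
N_PAIRS = 30
ENCODING_TRIALS = 60
RETRIEVAL_TRIALS = 42

# Anchor countries printed with their delays; ranks are positions (1-based)
# in the distance-from-Seoul ordering of the bundled 30-country lexicon.
ANCHOR_COUNTRIES: dict[int, str] = {
    1: "Japan", 10: "Vietnam", 21: "Taiwan",
    50: "The Philippines", 90: "New Zealand", 180: "Brazil",
}

# Synthetic lexicon: 30 countries in ascending distance-from-Seoul rank,
# with the six anchors fixed at the ranks their delays occupy once the
# non-target delays are drawn from the strata below.
_COUNTRIES: tuple[str, ...] = (
    "Japan", "China", "Mongolia", "Hong Kong", "Vietnam",
    "Laos", "Cambodia", "Thailand", "Myanmar", "Taiwan",
    "Malaysia", "Singapore", "Brunei", "Bangladesh", "Bhutan",
    "Nepal", "The Philippines", "India", "Sri Lanka", "Indonesia",
    "Kazakhstan", "Maldives", "New Zealand", "Australia", "Uzbekistan",
    "Iran", "Turkey", "Egypt", "Morocco", "Brazil",
)

# Non-target delays are drawn between consecutive targets with fixed
# per-stratum counts so every target delay keeps a fixed sorted rank
# (1, 5, 10, 17, 23, 30) and hence a fixed anchor country. Candidates
# exclude values within +/-1 of any target.
_NONTARGET_STRATA: tuple[tuple[int, range], ...] = (
    (3, range(3, 9)),      # between 1 and 10
    (4, range(12, 20)),    # between 10 and 21
    (6, range(23, 49)),    # between 21 and 50
    (5, range(52, 89)),    # between 50 and 90
    (6, range(100, 179)),  # between 90 and 180
)

# Synthetic office-supply lexicon for Control_AM, annotated with a word
# length standing in for the Korean syllable count; an item of length L
# replaces a delay with L digits.
_OFFICE_ITEMS: dict[int, tuple[str, ...]] = {
    1: ("pen", "glue", "ruler", "brush", "book", "clip"),
    2: ("eraser", "stapler", "scissors", "notebook", "marker", "folder",
        "binder", "sharpener", "envelope", "calculator", "ledger", "planner",
        "highlighter", "clipboard", "paperweight", "hole punch", "ink pad",
        "card holder", "tape roll", "pencil case"),
    3: ("mouse controller", "desk organizer", "paper shredder",
        "laminating film", "document tray", "monitor stand",
        "filing cabinet", "label printer"),
}


@dataclass(frozen=True)
class AssociationPair:
    """One country -> cue association (delay variant or control variant)."""

    country: str
    cue_value: int | str
    is_target: bool

    @property
    def cue_length(self) -> int:
        """Digit count of a delay cue, annotated word length of a control cue."""
        if isinstance(self.cue_value, int):
            return len(str(self.cue_value))
        return _office_length(self.cue_value)


def _office_length(label: str) -> int:
    for length, items in _OFFICE_ITEMS.items():
        if label in items:
            return length
    raise KeyError(f"unknown office item {label!r}")


@dataclass(frozen=True)
class AMSchedule:
    variant: Literal["delay", "control"]
    pairs: tuple[AssociationPair, ...]
    encoding: tuple[AssociationPair, ...]
    retrieval: tuple[AssociationPair, ...]


def _draw_delays(rng: np.random.Generator) -> list[int]:
    """All 30 delays in ascending order (6 targets + 24 sampled non-targets)."""
    delays = list(TARGET_DELAYS)
    for count, candidates in _NONTARGET_STRATA:
        delays.extend(rng.choice(list(candidates), size=count, replace=False))
    return sorted(int(d) for d in delays)


def build_am_schedule(
    variant: Literal["delay", "control"] = "delay",
    rng: np.random.Generator | int | None = None,
) -> AMSchedule:
    """Build the encoding (60-trial) and retrieval (42-trial) schedules.

    Countries are matched to delays by ascending distance rank, which
    fixes the six printed anchor pairs. The control variant substitutes
    each delay with an office-supply item whose annotated word length
    equals the delay's digit count.
    """
    if variant not in ("delay", "control"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(rng)
    delays = _draw_delays(rng)
    pairs = [
        AssociationPair(country=c, cue_value=d, is_target=d in TARGET_DELAYS)
        for c, d in zip(_COUNTRIES, delays)
    ]
    if variant == "control":
        used: dict[int, list[str]] = {
            ln: list(rng.permutation(items)) for ln, items in _OFFICE_ITEMS.items()
        }
        pairs = [
            replace(p, cue_value=used[len(str(p.cue_value))].pop())
            for p in pairs
        ]
    encoding = list(pairs) * 2
    rng.shuffle(encoding)
    retrieval = [p for p in pairs for _ in (range(3) if p.is_target else range(1))]
    rng.shuffle(retrieval)
    assert len(encoding) == ENCODING_TRIALS and len(retrieval) == RETRIEVAL_TRIALS
    return AMSchedule(variant=variant, pairs=tuple(pairs),
                      encoding=tuple(encoding), retrieval=tuple(retrieval))


# ---------------------------------------------------------------------------
# Serial 7s working-memory task

INITIAL_RANGE = (107, 999)
RESET_FLOOR = 100
SERIAL7S_TIMEOUT_S = 20.0

Verdict = Literal["correct", "wrong", "timeout"]


@dataclass(frozen=True)
class Serial7sState:
    current_expected: int
    initial_number: int
    resets: int = 0
    correct_streak: int = 0


def new_serial7s_state(rng: np.random.Generator | int | None = None,
                       resets: int = 0) -> Serial7sState:
    rng = np.random.default_rng(rng)
    initial = int(rng.integers(INITIAL_RANGE[0], INITIAL_RANGE[1] + 1))
    return Serial7sState(current_expected=initial - 7, initial_number=initial,
                         resets=resets, correct_streak=0)


def serial7s_expected(previous_answer: int) -> int:
    """Next required answer: previous minus seven."""
    if previous_answer < RESET_FLOOR:
        raise ValueError(
            f"answers below {RESET_FLOOR} force a reset; got {previous_answer}")
    return previous_answer - 7


def serial7s_step(
    state: Serial7sState,
    response: int | None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Verdict, Serial7sState]:
    """Score one Serial-7s trial and advance (or reset) the task state.

    ``response=None`` encodes a timeout. The task resets — a fresh random
    initial number in [107, 999] — after a wrong answer, after a timeout,
    or after a correct answer whose successor would fall below 100.
    """
    rng = np.random.default_rng(rng)
    if response is None:
        return "timeout", new_serial7s_state(rng, resets=state.resets + 1)
    if response != state.current_expected:
        return "wrong", new_serial7s_state(rng, resets=state.resets + 1)
    nxt = state.current_expected - 7
    if nxt < RESET_FLOOR:
        return "correct", new_serial7s_state(rng, resets=state.resets + 1)
    return "correct", Serial7sState(
        current_expected=nxt,
        initial_number=state.initial_number,
        resets=state.resets,
        correct_streak=state.correct_streak + 1,
    )


@dataclass(frozen=True)
class Serial7sTrial:
    expected: int
    response: int | None
    verdict: Verdict


def simulate_serial7s_trace(
    p_correct: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> list[Serial7sTrial]:
    """Simulate a Serial-7s run from per-trial success probabilities.

    On each trial the agent answers correctly with the given probability;
    an incorrect answer is the expected value off by a small slip (so it
    scores "wrong", never "timeout"). Replaying the returned trials
    through :func:`serial7s_step` reproduces the verdicts.
    """
    rng = np.random.default_rng(rng)
    state = new_serial7s_state(rng)
    trials: list[Serial7sTrial] = []
    for p in p_correct:
        expected = state.current_expected
        if rng.random() < p:
            response = expected
        else:
            response = expected + int(rng.choice([-3, -1, 1, 3, 7]))
        verdict, state = serial7s_step(state, response, rng)
        trials.append(Serial7sTrial(expected=expected, response=response,
                                    verdict=verdict))
    return trials


# ---------------------------------------------------------------------------
# Control_WM spatial attention task

ATTENTION_DEADLINE_S = 1.5

Side = Literal["left", "right"]


def attention_score(
    stimulus_side: Side,
    response: Side | None,
    rt: float | None = None,
) -> Literal["correct", "incorrect", "timeout"]:
    """Score one spatial-attention trial (1.5 s response deadline)."""
    if stimulus_side not in ("left", "right"):
        raise ValueError(f"unknown stimulus side {stimulus_side!r}")
    if response is None or response == "none":
        return "timeout"
    if rt is not None and rt > ATTENTION_DEADLINE_S:
        return "timeout"
    if rt is not None and rt < 0:
        raise ValueError("reaction time must be non-negative")
    return "correct" if response == stimulus_side else "incorrect"
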