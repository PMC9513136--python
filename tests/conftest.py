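import numpy as np
import pytest

from itclab.cohort import simulate_agent_session
from itclab.model import DiscountParams
from itclab.staircase import StaircaseConfig


@pytest.fixture(scope="session")
def halving_config():
    return StaircaseConfig()


@pytest.fixture(scope="session")
def typical_params():
    """A mid-population agent: k = 0.01/day, mu = 10^-3.5 per KRW."""
    return DiscountParams(k=0.01, mu=10 ** -3.5)


@pytest.fixture(scope="session")
def typical_session(typical_params):
    return simulate_agent_session(typical_params, seed=11,
                                  participant_id="fixture")


def random_offer_fixture(n_trials, rng):
    """Small random trial set: softmax choices on random offers."""
    from itclab.model import p_immediate, subjective_value
    from itclab.staircase import DELAYS, TrialRecord

    k = 10 ** rng.uniform(-3, -1)
    mu = 10 ** rng.uniform(-4, -3)
    trials = []
    for i in range(n_trials):
        delayed = float(rng.integers(103, 294) * 100)
        delay = int(rng.choice(DELAYS))
        sv = subjective_value(delayed, delay, k)
        choice = "immediate" if rng.random() < p_immediate(10_000, sv, mu) else "delayed"
        trials.append(TrialRecord(
            participant_id="fx", phase="pre", block=1, trial_index=i + 1,
            delay_days=delay, immediate_reward=10_000.0, delayed_reward=delayed,
            arm_id=(delay, 15_000), step=1, choice=choice))
    return trials
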