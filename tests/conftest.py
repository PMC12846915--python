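import numpy as np
import pytest

import continualtwin as ct


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def near_schedule():
    return ct.build_schedule(ct.NEAR(), seed=5)


@pytest.fixture(scope="session")
def far_schedule():
    return ct.build_schedule(ct.FAR, seed=7)


@pytest.fixture(scope="session")
def same_schedule():
    return ct.build_schedule(ct.SAME, seed=9)


@pytest.fixture(scope="session")
def trained_rich_near(near_schedule):
    """One fully trained rich-regime network on a Near schedule (shared)."""
    return ct.TwinnedLinearNetwork(near_schedule, ct.TrainConfig.rich(seed=1)).fit()


@pytest.fixture(scope="session")
def trained_rich_far(far_schedule):
    return ct.TwinnedLinearNetwork(far_schedule, ct.TrainConfig.rich(seed=2)).fit()


@pytest.fixture(scope="session")
def trained_rich_same(same_schedule):
    return ct.TwinnedLinearNetwork(same_schedule, ct.TrainConfig.rich(seed=3)).fit()


def perfect_rule_a_log(schedule):
    """Response log of an idealised subject applying rule A in every phase.

    Summer responses are exact; winter responses apply rule A to the
    feedback just received for summer (the true summer location when
    feedback carries no noise).
    """
    import pandas as pd

    rows = []
    last_fb = {}
    rule_a = schedule.spec.rule_a
    for t in schedule.trials:
        if t.season == "summer":
            resp = t.target_deg
            if t.feedback_given:
                last_fb[t.stimulus_id] = t.feedback_deg
        else:
            resp = ct.wrap_deg(last_fb[t.stimulus_id] + rule_a)
        rows.append(
            {
                "trial_index": t.index,
                "repeat": 0,
                "phase": t.phase,
                "block": t.block,
                "stimulus_id": t.stimulus_id,
                "season": t.season,
                "response_deg": resp,
                "target_deg": t.target_deg,
                "feedback_given": t.feedback_given,
                "feedback_deg": t.feedback_deg,
            }
        )
    return pd.DataFrame(rows)


def uniform_log(schedule, rng):
    """Response log of a uniform random responder."""
    import pandas as pd

    rows = []
    for t in schedule.trials:
        rows.append(
            {
                "trial_index": t.index,
                "repeat": 0,
                "phase": t.phase,
                "block": t.block,
                "stimulus_id": t.stimulus_id,
                "season": t.season,
                "response_deg": float(rng.uniform(0, 360)),
                "target_deg": t.target_deg,
                "feedback_given": t.feedback_given,
                "feedback_deg": t.feedback_deg,
            }
        )
    return pd.DataFrame(rows)
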