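"""Synthetic behavioural agents with known ground-truth structure.

These agents emulate the generative structure the interference mixture
model assumes: after a learning-onset period they respond to summer probes
from a von Mises memory of the true location, and to winter probes by
applying the currently active rule to the feedback just received for
summer, with von Mises response noise.  At retest the active rule is rule B
with a per-trial probability ``pi_retest`` — the ground-truth interference
weight the analysis pipeline should recover.  A lapse parameter mixes in
uniform responses.

Because every parameter is known, cohorts of these agents provide
end-to-end parameter-recovery tests of the full behavioural pipeline
(rule-response extraction, EM mixture fitting, strategy classification)
without any human data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_deg
from .schedule import Condition, Schedule, build_schedule

__all__ = ["AgentParams", "simulate_agent", "simulate_cohort"]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic subject.

    ``strategy`` selects how winter probes are answered once learning has
    begun: ``rule_user`` applies the active rule to the preceding summer
    feedback, ``memorizer`` recalls the true winter location directly
    (never using the rule, so it cannot generalize to the test stimulus),
    ``random`` responds uniformly throughout.
    """

    strategy: str = "rule_user"
    pi_retest: float = 0.0  # probability of applying rule B at retest
    kappa_rule: float = 10.0  # concentration of rule-based winter responses
    kappa_memory: float = 10.0  # concentration of memorised summer responses
    lapse: float = 0.0  # probability of a uniform lapse response
    learning_onset: int = 1  # within-phase block after which learning is expressed

    def __post_init__(self):
        if self.strategy not in ("rule_user", "memorizer", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for p in (self.pi_retest, self.lapse):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.kappa_rule <= 0 or self.kappa_memory <= 0:
            raise ValueError("concentrations must be positive")


def _vm_deg(rng: np.random.Generator, mu_deg: float, kappa: float) -> float:
    return float(wrap_deg(np.rad2deg(rng.vonmises(np.deg2rad(mu_deg), kappa))))


def simulate_agent(schedule: Schedule, params: AgentParams, rng: np.random.Generator) -> pd.DataFrame:
    """One synthetic subject's response log for one schedule (single pass)."""
    spec = schedule.spec
    rows = []
    last_summer_feedback: dict[int, float] = {}
    for trial in schedule.trials:
        within_block = (trial.block - 1) % 10 + 1
        learned = within_block > params.learning_onset or trial.phase == "retestA"
        if params.strategy == "random" or rng.uniform() < params.lapse or not learned:
            response = float(rng.uniform(0.0, 360.0))
        elif trial.season == "summer":
            response = _vm_deg(rng, trial.target_deg, params.kappa_memory)
        elif params.strategy == "memorizer":
            response = _vm_deg(rng, trial.target_deg, params.kappa_memory)
        else:  # rule user, winter probe
            if trial.phase == "trainA":
                rule = spec.rule_a
            elif trial.phase == "trainB":
                rule = spec.rule_b
            else:  # retest: interference applies rule B with probability pi_retest
                rule = spec.rule_b if rng.uniform() < params.pi_retest else spec.rule_a
            anchor = last_summer_feedback.get(trial.stimulus_id, trial.target_deg - rule)
            response = _vm_deg(rng, anchor + rule, params.kappa_rule)
        if trial.season == "summer" and trial.feedback_given:
            last_summer_feedback[trial.stimulus_id] = trial.feedback_deg
        rows.append(
            {
                "trial_index": trial.index,
                "repeat": 0,
                "phase": trial.phase,
                "block": trial.block,
                "stimulus_id": trial.stimulus_id,
                "season": trial.season,
                "response_deg": response,
                "target_deg": trial.target_deg,
                "feedback_given": trial.feedback_given,
                "feedback_deg": trial.feedback_deg,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    condition: Condition,
    n: int,
    params_distribution,
    seed: int,
) -> tuple[list[pd.DataFrame], list[Schedule], pd.DataFrame]:
    """Independent schedules and agents, plus a ground-truth table.

    ``params_distribution`` is either a fixed :class:`AgentParams` applied
    to every subject or a callable ``rng -> AgentParams`` sampling new
    parameters per subject.  Returns (logs, schedules, truth) where *truth*
    records each subject's generative parameters for recovery scoring.
    """
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    seeds = np.random.SeedSequence(seed).spawn(n)
    logs: list[pd.DataFrame] = []
    schedules: list[Schedule] = []
    truth_rows = []
    for i, ss in enumerate(seeds):
        child = ss.generate_state(2)
        schedule = build_schedule(condition, int(child[0] % (2**31)))
        rng = np.random.default_rng(ss)
        params = params_distribution(rng) if callable(params_distribution) else params_distribution
        logs.append(simulate_agent(schedule, params, rng))
        schedules.append(schedule)
        truth_rows.append(
            {
                "subject": i,
                "condition": schedule.condition.label,
                "strategy": params.strategy,
                "pi_retest": params.pi_retest,
                "kappa_rule": params.kappa_rule,
                "kappa_memory": params.kappa_memory,
                "lapse": params.lapse,
                "learning_onset": params.learning_onset,
                "rule_a": schedule.spec.rule_a,
                "rule_b": schedule.spec.rule_b,
                "true_label": "lumper" if params.pi_retest >= 0.5 else "splitter",
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject", "condition", "strategy", "pi_retest", "kappa_rule",
            "kappa_memory", "lapse", "learning_onset", "rule_a", "rule_b", "true_label",
        ],
    )
    return logs, schedules, truth
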