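"""Scalar behavioural measures computed from any response log.

A response log is a tidy DataFrame with one row per probe, the common
currency between network simulations, synthetic agents, and externally
supplied human-format data.  Required columns:

    phase, block, repeat, stimulus_id, season, response_deg, target_deg,
    feedback_given, feedback_deg

``repeat`` is the training-pass index (always 0 for single-pass subjects
such as humans or synthetic agents).  Blocks are labelled globally 1-30
(task A training 1-10, task B training 11-20, task A retest 21-30).

Accuracy normalises absolute circular error by its maximum (180 degrees),
so chance (uniform responding, expected error 90 degrees) sits at 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circular_error, signed_diff_deg

__all__ = [
    "accuracy",
    "points",
    "rule_response",
    "rule_responses",
    "transfer",
    "generalization",
    "summer_accuracy",
    "exceeds_chance",
    "block_accuracy",
    "MetricsReport",
    "compute_metrics",
]

LAST_TRAINA_BLOCK = 10
FIRST_TRAINB_BLOCK = 11
POINTS_CUTOFF_DEG = 30.0
CHANCE_ACCURACY = 0.5


def accuracy(error_deg):
    """Normalised accuracy 1 - error/180 for errors in [0, 180]."""
    err = np.asarray(error_deg, dtype=float)
    if np.any((err < 0) | (err > 180)):
        raise ValueError("circular error must lie in [0, 180] degrees")
    out = 1.0 - err / 180.0
    return out if out.ndim else float(out)


def points(error_deg):
    """Per-trial points: round(log(1/error^2)), floored at 0, capped at 10.

    Natural log; errors of 30 degrees or more earn nothing.  Rounding is
    ties-to-even (the numpy default).
    """
    err = np.asarray(error_deg, dtype=float)
    with np.errstate(divide="ignore"):
        raw = np.round(np.log(1.0 / err**2))
    pts = np.clip(raw, 0, 10)
    pts = np.where(err >= POINTS_CUTOFF_DEG, 0, pts)
    pts = np.where(err == 0, 10, pts)  # log cap: arbitrarily small error maxes out
    out = pts.astype(int)
    return out if out.ndim else int(out)


def rule_response(winter_response, prev_summer_feedback):
    """Signed offset (winter response - preceding summer feedback).

    Computed on the ground-truth winter location with noiseless feedback
    this equals the task rule, so the distribution of rule responses around
    the two rules is what the interference mixture model is fitted to.
    """
    return signed_diff_deg(winter_response, prev_summer_feedback)


def _require_columns(log: pd.DataFrame):
    missing = {"phase", "block", "season", "stimulus_id", "response_deg", "target_deg"} - set(log.columns)
    if missing:
        raise ValueError(f"response log is missing columns {sorted(missing)}")


def _with_repeat(log: pd.DataFrame) -> pd.DataFrame:
    if "repeat" not in log.columns:
        log = log.copy()
        log["repeat"] = 0
    return log


def rule_responses(log: pd.DataFrame, phase: str, blocks=None) -> np.ndarray:
    """Per-winter-trial rule responses for one phase.

    Joins each winter row to the immediately preceding summer row of the
    same stimulus, block and repeat, and uses the feedback actually shown
    for that summer probe (falling back to the true summer location if the
    log carries no feedback angle).
    """
    _require_columns(log)
    log = _with_repeat(log)
    sub = log[log["phase"] == phase]
    if blocks is not None:
        sub = sub[sub["block"].isin(blocks)]
    keys = ["repeat", "block", "stimulus_id"]
    summer = sub[sub["season"] == "summer"].set_index(keys)
    winter = sub[sub["season"] == "winter"]
    if winter.empty:
        raise ValueError(f"no winter rows in phase {phase!r}")
    fb = summer["feedback_deg"] if "feedback_deg" in summer.columns else summer["target_deg"]
    fb = fb.fillna(summer["target_deg"])
    joined_fb = fb.loc[list(winter[keys].itertuples(index=False, name=None))].to_numpy()
    return np.asarray(rule_response(winter["response_deg"].to_numpy(), joined_fb))


def _winter_accuracy(rows: pd.DataFrame) -> float:
    if rows.empty:
        raise ValueError("empty metric window")
    return float(np.mean(accuracy(circular_error(rows["response_deg"], rows["target_deg"]))))


def transfer(log: pd.DataFrame) -> float:
    """Winter-accuracy change across the task A -> task B boundary.

    Mean winter accuracy in the first task B training block (first pass)
    minus mean winter accuracy in the final task A training block (final
    pass).  Negative values are the cost of switching to new stimuli.
    """
    _require_columns(log)
    log = _with_repeat(log)
    winter = log[log["season"] == "winter"]
    a = winter[(winter["phase"] == "trainA") & (winter["block"] == LAST_TRAINA_BLOCK)]
    b = winter[(winter["phase"] == "trainB") & (winter["block"] == FIRST_TRAINB_BLOCK)]
    if a.empty or b.empty:
        raise ValueError("transfer needs the last task A and first task B training blocks")
    a = a[a["repeat"] == a["repeat"].max()]
    b = b[b["repeat"] == b["repeat"].min()]
    return _winter_accuracy(b) - _winter_accuracy(a)


def generalization(log: pd.DataFrame, test_stimulus: int) -> float:
    """Winter accuracy for the held-out test stimulus, second half of task A.

    The test stimulus never receives winter feedback, so accurate winter
    responses can only come from applying the task rule to its summer
    location.  Averaged over blocks 6-10 of every task A training pass, to
    allow for rule learning first.
    """
    _require_columns(log)
    log = _with_repeat(log)
    rows = log[
        (log["phase"] == "trainA")
        & (log["season"] == "winter")
        & (log["stimulus_id"] == test_stimulus)
        & (log["block"] > LAST_TRAINA_BLOCK // 2)
    ]
    if rows.empty:
        raise ValueError("no test-stimulus winter rows in the second half of task A")
    return _winter_accuracy(rows)


def summer_accuracy(log: pd.DataFrame, blocks=None) -> float:
    """Mean summer accuracy over the first task A training pass.

    Summer locations cannot be inferred from a rule; they index memory for
    each stimulus individually.  Restricted to the first pass (120 trials)
    so network and human exposure match; ``blocks`` optionally narrows the
    window further.
    """
    _require_columns(log)
    log = _with_repeat(log)
    rows = log[(log["phase"] == "trainA") & (log["season"] == "summer")]
    rows = rows[rows["repeat"] == rows["repeat"].min()] if not rows.empty else rows
    if blocks is not None:
        rows = rows[rows["block"].isin(blocks)]
    if rows.empty:
        raise ValueError("empty summer-accuracy window")
    return _winter_accuracy(rows)  # same formula; rows are summer probes


def exceeds_chance(log: pd.DataFrame, alpha: float = 0.05) -> bool:
    """Did the subject beat chance in the final two task A training blocks?

    One-sided one-sample t-test of per-trial accuracies against 0.5 on the
    first pass of blocks 9-10 (both seasons).  A degenerate sample with zero
    variance decides by its mean.
    """
    _require_columns(log)
    log = _with_repeat(log)
    rows = log[
        (log["phase"] == "trainA")
        & (log["block"].isin([LAST_TRAINA_BLOCK - 1, LAST_TRAINA_BLOCK]))
    ]
    rows = rows[rows["repeat"] == rows["repeat"].min()]
    if rows.empty:
        raise ValueError("final two task A training blocks not present")
    acc = accuracy(circular_error(rows["response_deg"], rows["target_deg"]))
    acc = np.atleast_1d(acc)
    if np.ptp(acc) < 1e-9:  # constant sample: decide by its level
        return bool(acc.mean() > CHANCE_ACCURACY + 1e-9)
    t, p = stats.ttest_1samp(acc, CHANCE_ACCURACY, alternative="greater")
    return bool(p < alpha)


def block_accuracy(log: pd.DataFrame, season: str) -> pd.DataFrame:
    """Per-(phase, block) mean accuracy series for one season, first pass."""
    _require_columns(log)
    log = _with_repeat(log)
    rows = log[(log["season"] == season) & (log["repeat"] == log["repeat"].min())].copy()
    rows["accuracy"] = accuracy(circular_error(rows["response_deg"], rows["target_deg"]))
    return rows.groupby(["phase", "block"], sort=False)["accuracy"].mean().reset_index()


@dataclass
class MetricsReport:
    """Scalar behavioural profile of one subject-equivalent log."""

    transfer: float
    generalization: float
    summer_accuracy: float
    interference: float  # NaN for the Same condition (undefined there)
    winter_by_block: pd.DataFrame
    summer_by_block: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "transfer": self.transfer,
            "generalization": self.generalization,
            "summer_accuracy": self.summer_accuracy,
            "interference": self.interference,
        }


def compute_metrics(log: pd.DataFrame, schedule) -> MetricsReport:
    """Full behavioural profile of one log against its schedule.

    Interference (the fitted probability of using rule B at retest) is only
    defined when the rules differ, so it is NaN for Same-condition
    schedules.
    """
    from .mixture import interference  # late import: mixture depends on metrics

    spec = schedule.spec
    if schedule.condition.label == "same":
        pi = math.nan
    else:
        resp = rule_responses(log, "retestA")
        pi = interference(resp, spec.rule_a, spec.rule_b, condition=schedule.condition.label)
    return MetricsReport(
        transfer=transfer(log),
        generalization=generalization(log, spec.test_stimulus_index),
        summer_accuracy=summer_accuracy(log),
        interference=pi,
        winter_by_block=block_accuracy(log, "winter"),
        summer_by_block=block_accuracy(log, "summer"),
    )
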