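"""Cohort-level experiments: schedules -> twinned networks -> summaries.

``run_condition_experiment`` generates n subject-equivalent schedules for a
condition, trains one network per schedule in the requested initialisation
regime, and assembles per-subject behavioural metrics (transfer,
interference, generalization, summer accuracy) and representational
geometry (99%-variance dimensionality, principal angle) into a tidy table.
``aggregate_report`` reduces such tables to group means, standard errors
and comparison statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import generalization, summer_accuracy, transfer
from .mixture import interference
from .metrics import rule_responses
from .network import TrainConfig, TwinnedLinearNetwork
from .schedule import Condition, build_schedule
from .subspace import subspace_report

__all__ = [
    "CohortReport",
    "run_condition_experiment",
    "run_subject",
    "aggregate_report",
    "welch_ttest",
    "anova_oneway",
]

REGIMES = {"rich": TrainConfig.rich, "lazy": TrainConfig.lazy}


@dataclass
class CohortReport:
    """Per-subject rows plus group-level summaries for one cohort."""

    condition: str
    regime: str
    subjects: pd.DataFrame
    summary: pd.DataFrame
    failures: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def mean(self, metric: str) -> float:
        return float(self.subjects[metric].mean())


def run_subject(
    schedule, config: TrainConfig, subject_id: int = 0, keep_results: bool = False
) -> dict:
    """Train one twinned network and compute its full metric row."""
    results = TwinnedLinearNetwork(schedule, config).fit()
    log = results.responses
    spec = schedule.spec
    geometry = subspace_report(results)
    if schedule.condition.label == "same":
        pi = math.nan
    else:
        pi = interference(
            rule_responses(log, "retestA"), spec.rule_a, spec.rule_b,
            condition=schedule.condition.label,
        )
    row = {
        "subject": subject_id,
        "condition": schedule.condition.label,
        "seed": schedule.seed,
        "transfer": transfer(log),
        "interference": pi,
        "generalization": generalization(log, spec.test_stimulus_index),
        "summer_accuracy": summer_accuracy(log),
        "n99_after_A": geometry.n99_after_A,
        "n99_after_B": geometry.n99_after_B,
        "principal_angle_deg": geometry.principal_angle_deg,
        "loss_end_trainA": results.end_of_phase_loss("trainA"),
        "loss_end_trainB": results.end_of_phase_loss("trainB"),
    }
    if keep_results:
        row["results"] = results
    return row


def run_condition_experiment(
    condition: Condition,
    n: int,
    regime: str = "rich",
    seed: int = 0,
    config: TrainConfig | None = None,
) -> CohortReport:
    """Train and analyse a cohort of n twinned networks.

    Each subject gets an independent schedule (seeded from ``seed``) and a
    freshly initialised network.  Per-subject failures are recorded in
    ``failures`` rather than silently dropped.
    """
    if n < 2:
        raise ValueError("a cohort needs at least two subjects")
    if config is None:
        if regime not in REGIMES:
            raise ValueError(f"regime must be one of {sorted(REGIMES)}")
        config = REGIMES[regime]()
    seeds = np.random.SeedSequence(seed).spawn(n)
    rows, failures = [], []
    for i, ss in enumerate(seeds):
        state = ss.generate_state(2)
        sched_seed = int(state[0] % (2**31))
        net_seed = int(state[1] % (2**31))
        try:
            schedule = build_schedule(condition, sched_seed)
            row = run_subject(schedule, _with_seed(config, net_seed), subject_id=i)
            row["regime"] = regime
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - reported, not dropped
            failures.append({"subject": i, "error": repr(exc)})
    subjects = pd.DataFrame(rows)
    return CohortReport(
        condition=condition.label,
        regime=regime,
        subjects=subjects,
        summary=aggregate_report(subjects),
        failures=failures,
    )


def _with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return TrainConfig(
        hidden_units=config.hidden_units,
        learning_rate=config.learning_rate,
        repeats_per_phase=config.repeats_per_phase,
        sigma_embed=config.sigma_embed,
        sigma_readout=config.sigma_readout,
        seed=seed,
    )


_METRICS = [
    "transfer",
    "interference",
    "generalization",
    "summer_accuracy",
    "n99_after_A",
    "n99_after_B",
    "principal_angle_deg",
]


def aggregate_report(per_subject_rows: pd.DataFrame, group_cols=("condition", "regime")) -> pd.DataFrame:
    """Group means and standard errors, one row per (group, metric).

    Deterministic given the rows and invariant to row order.  Groups of a
    single subject get a NaN standard error and ``flagged=True``.
    """
    if per_subject_rows.empty:
        raise ValueError("no per-subject rows to aggregate")
    df = per_subject_rows.copy()
    group_cols = [c for c in group_cols if c in df.columns]
    if not group_cols:
        df["_all"] = "all"
        group_cols = ["_all"]
    records = []
    for keys, grp in df.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for metric in _METRICS:
            if metric not in grp.columns:
                continue
            vals = grp[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sem = float(stats.sem(vals)) if vals.size > 1 else math.nan
            rec = dict(zip(group_cols, keys))
            rec.update(
                metric=metric,
                n=int(vals.size),
                mean=float(vals.mean()),
                sem=sem,
                flagged=vals.size < 2,
            )
            records.append(rec)
    return pd.DataFrame(records)


def welch_ttest(x, y, alternative: str = "two-sided") -> dict:
    """Welch two-sample t-test annotation for group comparisons."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return {"t": float(t), "p": float(p), "n_x": x.size, "n_y": y.size}


def anova_oneway(*groups) -> dict:
    """One-way ANOVA annotation across condition groups."""
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return {"F": float(f), "p": float(p)}
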