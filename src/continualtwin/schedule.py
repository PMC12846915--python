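"""Generation of participant-equivalent task schedules.

A schedule describes one subject's full experiment: two tasks of six stimuli
each, mapped to locations on a circle in two seasonal contexts.  Within a
task, each stimulus' winter location is its summer location rotated by a
fixed angular *rule*.  Subjects (humans, synthetic agents or twinned
networks) are trained on task A, then task B, then retested on task A, with
winter feedback withheld at retest and, throughout, for one designated test
stimulus.

The relationship between the two task rules defines the condition:

- ``Same``  rule B = rule A
- ``Near``  rule B = rule A ± 30° (sign randomised per subject)
- ``Far``   rule B = rule A + 180°
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_deg

__all__ = [
    "Condition",
    "TaskSpec",
    "Trial",
    "Schedule",
    "SAME",
    "FAR",
    "sample_rule_a",
    "derive_rule_b",
    "sample_stimulus_locations",
    "build_schedule",
    "load_schedule",
]

N_STIMULI = 6
BLOCKS_PER_PHASE = 10
TRIALS_PER_BLOCK = 2 * N_STIMULI
PHASES = ("trainA", "trainB", "retestA")
#: admissible arcs for the task A rule (degrees, inclusive)
RULE_A_ARCS = ((60.0, 150.0), (210.0, 300.0))
FEEDBACK_SD = 5.0  # s.d. of the Gaussian noise shown on feedback, degrees
JITTER_SD = 15.0  # s.d. of stimulus placement jitter around the 60° lattice


@dataclass(frozen=True)
class Condition:
    """Task-similarity condition.

    ``near_sign`` is the direction of the ±30° rule shift and is only
    meaningful for the Near condition; ``None`` means "sample a fair sign
    when the schedule is built".
    """

    label: str
    near_sign: int | None = None

    def __post_init__(self):
        if self.label not in ("same", "near", "far"):
            raise ValueError(f"unknown condition label {self.label!r}")
        if self.label == "near" and self.near_sign not in (None, 1, -1):
            raise ValueError("near_sign must be +1, -1 or None")
        if self.label != "near" and self.near_sign is not None:
            raise ValueError("near_sign only applies to the Near condition")

    @property
    def rule_shift(self) -> float | None:
        """Signed rule change from task A to task B, or None if unresolved."""
        if self.label == "same":
            return 0.0
        if self.label == "far":
            return 180.0
        return None if self.near_sign is None else 30.0 * self.near_sign


SAME = Condition("same")
FAR = Condition("far")


def NEAR(sign: int | None = None) -> Condition:
    return Condition("near", sign)


def _in_rule_a_arcs(angle: float) -> bool:
    return any(lo <= angle <= hi for lo, hi in RULE_A_ARCS)


def sample_rule_a(rng: np.random.Generator) -> float:
    """Draw the task A rule uniformly over the two admissible arcs.

    Both arcs span 90°, so each carries probability mass 1/2.
    """
    u = rng.uniform(0.0, 180.0)
    if u < 90.0:
        return 60.0 + u
    return 210.0 + (u - 90.0)


def derive_rule_b(rule_a: float, condition: Condition, rng: np.random.Generator | None = None) -> float:
    """Task B rule implied by ``rule_a`` and the condition.

    For Near conditions with an unresolved sign a fair Bernoulli sign is
    drawn from ``rng``.
    """
    if not _in_rule_a_arcs(rule_a):
        raise ValueError(f"rule_a={rule_a} outside the admissible arcs {RULE_A_ARCS}")
    if condition.label == "same":
        return float(rule_a)
    if condition.label == "far":
        return float(wrap_deg(rule_a + 180.0))
    sign = condition.near_sign
    if sign is None:
        if rng is None:
            raise ValueError("Near condition with unresolved sign requires an rng")
        sign = int(rng.choice([-1, 1]))
    return float(wrap_deg(rule_a + 30.0 * sign))


def sample_stimulus_locations(rng: np.random.Generator, jitter_sd: float = JITTER_SD) -> np.ndarray:
    """Six summer locations: a rotated 60° lattice with Gaussian jitter.

    A uniform base offset rotates the whole lattice (placement is randomised
    per subject and task), then each position receives independent Gaussian
    jitter with the given s.d. before reduction mod 360.
    """
    offset = rng.uniform(0.0, 360.0)
    lattice = offset + 60.0 * np.arange(N_STIMULI)
    return wrap_deg(lattice + rng.normal(0.0, jitter_sd, size=N_STIMULI))


@dataclass(frozen=True)
class TaskSpec:
    """Rules and stimulus placements for one subject's pair of tasks."""

    rule_a: float
    rule_b: float
    summer_a: np.ndarray  # 6 summer locations for task A stimuli (ids 0-5)
    summer_b: np.ndarray  # 6 summer locations for task B stimuli (ids 6-11)
    test_stimulus_index: int  # task A stimulus id whose winter feedback is withheld

    def __post_init__(self):
        if not _in_rule_a_arcs(self.rule_a):
            raise ValueError("rule_a outside admissible arcs")
        if not 0 <= self.test_stimulus_index < N_STIMULI:
            raise ValueError("test stimulus must be a task A stimulus (0-5)")
        for name in ("summer_a", "summer_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_STIMULI,):
                raise ValueError(f"{name} must hold {N_STIMULI} angles")
            object.__setattr__(self, name, arr)

    @property
    def winter_a(self) -> np.ndarray:
        return wrap_deg(self.summer_a + self.rule_a)

    @property
    def winter_b(self) -> np.ndarray:
        return wrap_deg(self.summer_b + self.rule_b)

    def summer_location(self, stimulus_id: int) -> float:
        if 0 <= stimulus_id < N_STIMULI:
            return float(self.summer_a[stimulus_id])
        return float(self.summer_b[stimulus_id - N_STIMULI])

    def winter_location(self, stimulus_id: int) -> float:
        if 0 <= stimulus_id < N_STIMULI:
            return float(self.winter_a[stimulus_id])
        return float(self.winter_b[stimulus_id - N_STIMULI])

    def to_dict(self) -> dict:
        return {
            "rule_a": self.rule_a,
            "rule_b": self.rule_b,
            "summer_a": [float(x) for x in self.summer_a],
            "summer_b": [float(x) for x in self.summer_b],
            "test_stimulus_index": int(self.test_stimulus_index),
        }


@dataclass(frozen=True)
class Trial:
    index: int  # position within the schedule, 0-based
    phase: str
    block: int  # global block label, 1-30
    stimulus_id: int  # 0-5 task A, 6-11 task B
    season: str  # "summer" | "winter"
    target_deg: float
    feedback_given: bool
    feedback_deg: float  # NaN when feedback is withheld


@dataclass(frozen=True)
class Schedule:
    condition: Condition
    spec: TaskSpec
    trials: tuple[Trial, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """One row per trial, in presentation order."""
        return pd.DataFrame(
            {
                "trial_index": [t.index for t in self.trials],
                "phase": [t.phase for t in self.trials],
                "block": [t.block for t in self.trials],
                "stimulus_id": [t.stimulus_id for t in self.trials],
                "season": [t.season for t in self.trials],
                "target_deg": [t.target_deg for t in self.trials],
                "feedback_given": [t.feedback_given for t in self.trials],
                "feedback_deg": [t.feedback_deg for t in self.trials],
            }
        )

    def to_csv(self) -> str:
        # %.17g keeps the round trip through text exact
        return self.to_frame().to_csv(index=False, float_format="%.17g")

    def save(self, directory: str | Path) -> None:
        """Write trials.csv plus a spec.json side-car."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "trials.csv").write_text(self.to_csv())
        sidecar = {
            "condition": self.condition.label,
            "near_sign": self.condition.near_sign,
            "seed": int(self.seed),
            "spec": self.spec.to_dict(),
        }
        (directory / "spec.json").write_text(json.dumps(sidecar, indent=2))


def load_schedule(directory: str | Path) -> Schedule:
    directory = Path(directory)
    sidecar = json.loads((directory / "spec.json").read_text())
    spec = TaskSpec(
        rule_a=sidecar["spec"]["rule_a"],
        rule_b=sidecar["spec"]["rule_b"],
        summer_a=np.array(sidecar["spec"]["summer_a"]),
        summer_b=np.array(sidecar["spec"]["summer_b"]),
        test_stimulus_index=sidecar["spec"]["test_stimulus_index"],
    )
    condition = Condition(sidecar["condition"], sidecar["near_sign"])
    frame = pd.read_csv(directory / "trials.csv", float_precision="round_trip")
    trials = tuple(
        Trial(
            index=int(r.trial_index),
            phase=r.phase,
            block=int(r.block),
            stimulus_id=int(r.stimulus_id),
            season=r.season,
            target_deg=float(r.target_deg),
            feedback_given=bool(r.feedback_given),
            feedback_deg=float(r.feedback_deg),
        )
        for r in frame.itertuples()
    )
    return Schedule(condition=condition, spec=spec, trials=trials, seed=int(sidecar["seed"]))


def _phase_stimulus_ids(phase: str) -> np.ndarray:
    if phase == "trainB":
        return np.arange(N_STIMULI, 2 * N_STIMULI)
    return np.arange(N_STIMULI)


def build_schedule(
    condition: Condition,
    seed: int,
    feedback_sd: float = FEEDBACK_SD,
    jitter_sd: float = JITTER_SD,
) -> Schedule:
    """Build one subject-equivalent schedule.

    Three phases (task A training, task B training, task A retest) of 10
    blocks each; a block presents each of the phase's six stimuli once per
    season, with stimulus order randomised within the block and a stimulus'
    summer probe always immediately preceding its winter probe.  Feedback is
    the true location plus Gaussian display noise, withheld on winter probes
    of the test stimulus (all phases) and on all winter probes at retest.
    """
    rng = np.random.default_rng(seed)
    rule_a = sample_rule_a(rng)
    if condition.label == "near" and condition.near_sign is None:
        condition = Condition("near", int(rng.choice([-1, 1])))
    rule_b = derive_rule_b(rule_a, condition, rng)
    spec = TaskSpec(
        rule_a=rule_a,
        rule_b=rule_b,
        summer_a=sample_stimulus_locations(rng, jitter_sd),
        summer_b=sample_stimulus_locations(rng, jitter_sd),
        test_stimulus_index=int(rng.integers(N_STIMULI)),
    )

    trials: list[Trial] = []
    index = 0
    for phase_i, phase in enumerate(PHASES):
        stim_ids = _phase_stimulus_ids(phase)
        for block_i in range(BLOCKS_PER_PHASE):
            block = phase_i * BLOCKS_PER_PHASE + block_i + 1
            for sid in rng.permutation(stim_ids):
                sid = int(sid)
                for season in ("summer", "winter"):
                    target = spec.summer_location(sid) if season == "summer" else spec.winter_location(sid)
                    withheld = season == "winter" and (
                        phase == "retestA" or sid == spec.test_stimulus_index
                    )
                    if withheld:
                        fb = math.nan
                    else:
                        fb = float(wrap_deg(target + rng.normal(0.0, feedback_sd)))
                    trials.append(
                        Trial(
                            index=index,
                            phase=phase,
                            block=block,
                            stimulus_id=sid,
                            season=season,
                            target_deg=float(target),
                            feedback_given=not withheld,
                            feedback_deg=fb,
                        )
                    )
                    index += 1
    return Schedule(condition=condition, spec=spec, trials=tuple(trials), seed=int(seed))
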