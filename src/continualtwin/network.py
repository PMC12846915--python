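"""Twinned two-layer linear networks trained online on task schedules.

The network maps 12 one-hot inputs (six stimuli per task) through a hidden
layer (default 50 units) to 4 linear outputs holding the Cartesian
coordinates of the summer and winter locations, ordered
(sin summer, cos summer, sin winter, cos winter).  Training is online
stochastic gradient descent on a masked squared error: on each trial only
the probed season's output pair is penalised,

    L = 1/2 [ (x_hat - sin theta)^2 + (y_hat - cos theta)^2 ],

with noiseless targets.  Trials without feedback produce no update, and
weights are never reset between phases, so interference between tasks can
only be avoided representationally.

The initialisation scale of the embedding weights selects the learning
regime: small weights (sigma = 1e-3) give *rich* learning (structured,
low-dimensional hidden representations), large weights (sigma = 2) give
*lazy* learning (random high-dimensional projections).  Readout weights are
always initialised small so the readout stays free to learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import wrap_deg
from .schedule import PHASES, Schedule

__all__ = [
    "TrainConfig",
    "NetworkState",
    "TrainingResults",
    "TwinnedLinearNetwork",
    "init_network",
    "forward",
    "sgd_step",
    "output_to_angle",
    "train_on_schedule",
]

N_INPUTS = 12
N_OUTPUTS = 4
_SEASON_PAIR = {"summer": 0, "winter": 2}  # offset of the (sin, cos) output pair


@dataclass(frozen=True)
class TrainConfig:
    """Network and training hyperparameters.

    ``sigma_embed`` is the initial weight scale of the input->hidden layer
    and is the rich/lazy dial; ``sigma_readout`` stays small in both
    regimes.
    """

    hidden_units: int = 50
    learning_rate: float = 0.01
    repeats_per_phase: int = 100
    sigma_embed: float = 1e-3
    sigma_readout: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.hidden_units <= 0 or self.learning_rate <= 0:
            raise ValueError("hidden_units and learning_rate must be positive")
        if self.repeats_per_phase < 0 or self.sigma_embed < 0 or self.sigma_readout < 0:
            raise ValueError("repeats and init scales must be non-negative")

    @classmethod
    def rich(cls, **kw) -> "TrainConfig":
        return cls(sigma_embed=1e-3, **kw)

    @classmethod
    def lazy(cls, **kw) -> "TrainConfig":
        return cls(sigma_embed=2.0, **kw)


@dataclass
class NetworkState:
    """The two weight matrices of one network."""

    W_embed: np.ndarray  # hidden_units x 12
    W_readout: np.ndarray  # 4 x hidden_units

    def copy(self) -> "NetworkState":
        return NetworkState(self.W_embed.copy(), self.W_readout.copy())


def init_network(config: TrainConfig, rng: np.random.Generator | None = None) -> NetworkState:
    """Zero-mean Gaussian initialisation at the configured scales."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W_embed = rng.normal(0.0, config.sigma_embed, size=(config.hidden_units, N_INPUTS))
    W_readout = rng.normal(0.0, config.sigma_readout, size=(N_OUTPUTS, config.hidden_units))
    return NetworkState(W_embed, W_readout)


def forward(state: NetworkState, stimulus_id: int) -> np.ndarray:
    """All four outputs for a one-hot input; linear throughout."""
    if not 0 <= stimulus_id < N_INPUTS:
        raise ValueError(f"stimulus_id must be in 0..{N_INPUTS - 1}")
    return state.W_readout @ state.W_embed[:, stimulus_id]


def output_to_angle(outputs: np.ndarray, season: str) -> float:
    """Read the probed season's (sin, cos) pair out as an angle in [0, 360).

    The zero-output origin (undefined direction) maps to 0 by atan2
    convention.
    """
    p = _SEASON_PAIR[season]
    return float(wrap_deg(np.rad2deg(np.arctan2(outputs[p], outputs[p + 1]))))


def _trial_gradients(state, stimulus_id, pair, target_rad):
    h = state.W_embed[:, stimulus_id]
    out = state.W_readout[pair : pair + 2] @ h
    err = out - np.array([np.sin(target_rad), np.cos(target_rad)])
    g_embed = state.W_readout[pair : pair + 2].T @ err
    g_readout = np.outer(err, h)
    return err, g_embed, g_readout


def sgd_step(state: NetworkState, trial, learning_rate: float = 0.01) -> tuple[NetworkState, float]:
    """One online update; returns the new state and the pre-update response.

    The response (in degrees) is always recorded from the pre-update
    forward pass; weights change only when the trial carries feedback, and
    both layers are updated simultaneously from the same gradient.  Targets
    are the noiseless sin/cos of the true location.
    """
    pair = _SEASON_PAIR[trial.season]
    outputs = forward(state, trial.stimulus_id)
    response = output_to_angle(outputs, trial.season)
    if not trial.feedback_given:
        return state, response
    _, g_embed, g_readout = _trial_gradients(state, trial.stimulus_id, pair, np.deg2rad(trial.target_deg))
    new = state.copy()
    new.W_readout[pair : pair + 2] -= learning_rate * g_readout
    new.W_embed[:, trial.stimulus_id] -= learning_rate * g_embed
    return new, response


class TwinnedLinearNetwork:
    """Model object: a linear network twinned to one task schedule.

    Mirrors the statsmodels pattern: the model holds the data (schedule) and
    configuration; :meth:`fit` runs the full three-phase online training
    protocol and returns a :class:`TrainingResults`.
    """

    def __init__(self, schedule: Schedule, config: TrainConfig | None = None):
        self.schedule = schedule
        self.config = config or TrainConfig()
        frame = schedule.to_frame()
        self._stim = frame["stimulus_id"].to_numpy()
        self._pair = np.where(frame["season"].to_numpy() == "winter", 2, 0)
        self._fb = frame["feedback_given"].to_numpy(dtype=bool)
        rad = np.deg2rad(frame["target_deg"].to_numpy(dtype=float))
        self._target_sc = np.column_stack([np.sin(rad), np.cos(rad)])
        self._phase = frame["phase"].to_numpy()
        self._frame = frame

    def fit(self, start_state: NetworkState | None = None) -> "TrainingResults":
        cfg = self.config
        state = start_state.copy() if start_state is not None else init_network(cfg)
        We, Wr = state.W_embed, state.W_readout
        eta = cfg.learning_rate
        stim, pair, fb, target_sc = self._stim, self._pair, self._fb, self._target_sc

        n_trials = len(stim)
        reps = cfg.repeats_per_phase
        responses = np.empty(n_trials * reps)
        losses = np.empty(n_trials * reps)
        snapshots: dict[str, NetworkState] = {}
        phase_slices = {ph: np.flatnonzero(self._phase == ph) for ph in PHASES}

        row = 0
        rows_trial = np.empty(n_trials * reps, dtype=np.int64)
        rows_repeat = np.empty(n_trials * reps, dtype=np.int64)
        for phase in PHASES:
            idx = phase_slices[phase]
            for rep in range(reps):
                for t in idx:
                    s = stim[t]
                    p = pair[t]
                    h = We[:, s]
                    Wr_p = Wr[p : p + 2]
                    out = Wr_p @ h
                    err = out - target_sc[t]
                    responses[row] = np.arctan2(out[0], out[1])
                    losses[row] = 0.5 * (err @ err)
                    rows_trial[row] = t
                    rows_repeat[row] = rep
                    row += 1
                    if fb[t]:
                        g_embed = Wr_p.T @ err
                        Wr[p : p + 2] -= eta * np.outer(err, h)
                        We[:, s] -= eta * g_embed
            snapshots[phase] = NetworkState(We.copy(), Wr.copy())

        responses = responses[:row]
        response_deg = wrap_deg(np.rad2deg(responses))
        meta = self._frame.iloc[rows_trial[:row]].reset_index(drop=True)
        log = pd.DataFrame(
            {
                "trial_index": meta["trial_index"],
                "repeat": rows_repeat[:row],
                "phase": meta["phase"],
                "block": meta["block"],
                "stimulus_id": meta["stimulus_id"],
                "season": meta["season"],
                "response_deg": response_deg,
                "target_deg": meta["target_deg"],
                "feedback_given": meta["feedback_given"],
                "feedback_deg": meta["feedback_deg"],
            }
        )
        loss_trace = self._loss_trace(log, losses[:row])
        return TrainingResults(
            model=self,
            state=NetworkState(We, Wr),
            responses=log,
            loss_trace=loss_trace,
            phase_states=snapshots,
        )

    @staticmethod
    def _loss_trace(log: pd.DataFrame, losses: np.ndarray) -> pd.DataFrame:
        """Mean pre-update loss over each pass's feedback trials."""
        df = log[["phase", "repeat", "feedback_given"]].copy()
        df["loss"] = losses
        df = df[df["feedback_given"]]
        out = df.groupby(["phase", "repeat"], sort=False)["loss"].mean().reset_index()
        return out.rename(columns={"loss": "mean_loss"})


@dataclass
class TrainingResults:
    """Trained weights plus the full pre-update response log.

    ``responses`` has one row per (trial, repeat) in training order, with
    responses recorded *before* each weight update, mirroring the
    respond-then-see-feedback structure of the behavioural task.
    ``phase_states`` holds a copy of the full weights at the end of each
    phase, for representational analyses after task A vs after task B.
    """

    model: TwinnedLinearNetwork
    state: NetworkState
    responses: pd.DataFrame
    loss_trace: pd.DataFrame
    phase_states: dict

    @property
    def schedule(self) -> Schedule:
        return self.model.schedule

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    def end_of_phase_loss(self, phase: str) -> float:
        """Mean training loss over the final pass of a phase."""
        tr = self.loss_trace
        sub = tr[tr["phase"] == phase]
        if sub.empty:
            raise ValueError(f"no passes recorded for phase {phase!r}")
        return float(sub.loc[sub["repeat"].idxmax(), "mean_loss"])

    def plot_loss(self, ax=None):
        """Mean per-pass training loss across the three phases."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        offset = 0
        for phase in PHASES:
            sub = self.loss_trace[self.loss_trace["phase"] == phase]
            ax.plot(offset + np.arange(len(sub)), sub["mean_loss"], label=phase)
            offset += len(sub)
        ax.set_xlabel("training pass")
        ax.set_ylabel("mean loss")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Twinned linear network training results",
            "=" * 42,
            f"condition:        {self.schedule.condition.label}",
            f"hidden units:     {cfg.hidden_units}",
            f"sigma_embed:      {cfg.sigma_embed:g}",
            f"repeats/phase:    {cfg.repeats_per_phase}",
        ]
        for phase in PHASES:
            try:
                lines.append(f"final {phase} loss: {self.end_of_phase_loss(phase):.3e}")
            except ValueError:
                pass
        return "\n".join(lines)


def train_on_schedule(
    config: TrainConfig, schedule: Schedule, start_state: NetworkState | None = None
) -> TrainingResults:
    """Functional wrapper around :class:`TwinnedLinearNetwork`."""
    return TwinnedLinearNetwork(schedule, config).fit(start_state)
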