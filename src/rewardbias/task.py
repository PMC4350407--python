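"""Task design: trial schedules for the two-context motion-discrimination reward task.

The scanner task crosses 2 reward contexts with 7 signed coherence levels
(0, +/-4, +/-12, +/-64 %), 20 repetitions per cell, for 280 trials spread
evenly over 5 runs.  Each trial is cue (1 s) -> random-dot stimulus (200 ms)
-> response window (800 ms from stimulus onset) -> reward feedback (1.5 s),
preceded by a truncated-exponential inter-trial interval (mean 4 s, range
2.7-12.7 s).  Payoffs are asymmetric and opposite between the two contexts:
in one context correct "up" choices earn the high payoff, in the other
correct "down" choices do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncexpon

# Direction codes used throughout: 1 = up (m1), 0 = down (m0), -1 = no response.
UP = 1
DOWN = 0
NO_RESPONSE = -1

#: Column order of the serialized trial table.
TRIAL_COLUMNS = [
    "participant_id", "run", "trial_index", "context", "coherence",
    "correct_direction", "onset_cue_s", "onset_stim_s", "onset_feedback_s",
    "iti_s",
]


class ConfigError(ValueError):
    """Raised when a TaskConfig violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the scanner task.

    Coherences are signed proportions in [-1, 1] (positive = upward motion);
    64% coherent upward motion is +0.64.  ``high_reward_direction`` maps each
    context label to the direction whose *correct* choice earns the high
    payoff; the mapping must differ between the two contexts.
    """

    n_contexts: int = 2
    coherence_levels: tuple[float, ...] = (-0.64, -0.12, -0.04, 0.0, 0.04, 0.12, 0.64)
    reps_per_cell: int = 20
    n_runs: int = 5
    high_reward_direction: tuple[int, ...] = (UP, DOWN)  # context 0 favours up
    payoff_high: float = 2.0
    payoff_low: float = 1.0
    payoff_incorrect: float = 0.0
    iti_mean_s: float = 4.0
    iti_min_s: float = 2.7
    iti_max_s: float = 12.7
    cue_duration_s: float = 1.0
    stim_duration_s: float = 0.2
    response_window_s: float = 0.8
    feedback_duration_s: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        levels = np.asarray(self.coherence_levels, dtype=float)
        if 0.0 not in levels:
            raise ConfigError("coherence_levels must include 0")
        if not np.allclose(np.sort(levels), np.sort(-levels)):
            raise ConfigError("coherence_levels must be symmetric about 0")
        if np.any(np.abs(levels) > 1):
            raise ConfigError("coherences are signed proportions in [-1, 1]")
        n_cells = self.n_contexts * len(levels)
        if (n_cells * self.reps_per_cell) % self.n_runs:
            raise ConfigError(
                f"total trial count {n_cells * self.reps_per_cell} is not "
                f"divisible by n_runs={self.n_runs}"
            )
        if self.n_contexts == 2 and len(set(self.high_reward_direction[:2])) != 2:
            raise ConfigError("payoff asymmetry must be opposite between contexts")
        if not (self.iti_min_s <= self.iti_mean_s <= self.iti_max_s):
            raise ConfigError("require iti_min <= iti_mean <= iti_max")

    @property
    def n_trials(self) -> int:
        return self.n_contexts * len(self.coherence_levels) * self.reps_per_cell

    @property
    def trials_per_run(self) -> int:
        return self.n_trials // self.n_runs

    def replace(self, **kwargs) -> "TaskConfig":
        return dataclasses.replace(self, **kwargs)


#: Practice-session variant: 9 coherence levels, 60 repetitions, six 90-trial
#: blocks, no reward contexts or payoffs.
PRACTICE_COHERENCES = (-0.80, -0.64, -0.12, -0.06, 0.0, 0.06, 0.12, 0.64, 0.80)


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered per-trial design (one row per trial) plus its config."""

    trials: pd.DataFrame
    config: TaskConfig

    def __len__(self) -> int:
        return len(self.trials)

    def run_trials(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run]


# --------------------------------------------------------------------------
# ITI sampling: exponential shifted to iti_min, truncated at iti_max, with
# the rate solved so the truncated mean equals iti_mean.
# --------------------------------------------------------------------------

def _truncated_exp_mean(rate: float, span: float) -> float:
    # mean of Exp(rate) truncated to [0, span]
    if rate * span > 700.0:
        return 1.0 / rate
    e = np.expm1(rate * span)  # exp(rate*span) - 1
    return 1.0 / rate - span / e


@lru_cache(maxsize=64)
def _solve_iti_rate(mean: float, lo: float, hi: float) -> float:
    span = hi - lo
    target = mean - lo
    if not (0.0 < target < span / 2.0):
        raise ConfigError(
            f"truncated-exponential mean {mean} unattainable on [{lo}, {hi}]"
        )
    return brentq(lambda r: _truncated_exp_mean(r, span) - target, 1e-8, 1e4,
                  xtol=1e-12, rtol=1e-14)


def iti_distribution(config: TaskConfig):
    """The frozen scipy distribution of the inter-trial interval."""
    lo, hi, mean = config.iti_min_s, config.iti_max_s, config.iti_mean_s
    if hi == lo:
        return None  # degenerate: every draw equals lo
    rate = _solve_iti_rate(mean, lo, hi)
    return truncexpon(b=(hi - lo) * rate, loc=lo, scale=1.0 / rate)


def sample_iti(config: TaskConfig, rng: np.random.Generator, size: int | None = None):
    """Draw inter-trial interval(s) in seconds.

    The rate of the shifted, truncated exponential is solved (once per
    configuration, cached) so that the truncated mean equals
    ``config.iti_mean_s``.
    """
    dist = iti_distribution(config)
    if dist is None:
        return config.iti_min_s if size is None else np.full(size, config.iti_min_s)
    return dist.rvs(size=size, random_state=rng)


# --------------------------------------------------------------------------
# Schedule construction
# --------------------------------------------------------------------------

def _allocate_cells_to_runs(cells: list[tuple], reps: int, n_runs: int,
                            rng: np.random.Generator) -> list[list[tuple]]:
    """Deal ``reps`` copies of every cell across runs as evenly as possible."""
    base, rem = divmod(reps, n_runs)
    per_run: list[list[tuple]] = [[] for _ in range(n_runs)]
    for r in range(n_runs):
        for cell in cells:
            per_run[r].extend([cell] * base)
    if rem:
        leftovers = [cell for cell in cells for _ in range(rem)]
        rng.shuffle(leftovers)
        sizes = np.array([len(p) for p in per_run])
        target = (len(cells) * reps) // n_runs
        for cell in leftovers:
            r = int(np.argmin(sizes - target))
            per_run[r].append(cell)
            sizes[r] += 1
    return per_run


def _timeline(n: int, config: TaskConfig, rng: np.random.Generator):
    itis = np.atleast_1d(sample_iti(config, rng, size=n)).astype(float)
    onset_cue = np.empty(n)
    t = 0.0
    trial_span = (config.cue_duration_s + config.response_window_s
                  + config.feedback_duration_s)
    for i in range(n):
        onset_cue[i] = t + itis[i]
        t = onset_cue[i] + trial_span
    onset_stim = onset_cue + config.cue_duration_s
    onset_feedback = onset_stim + config.response_window_s
    return itis, onset_cue, onset_stim, onset_feedback


def build_trial_schedule(config: TaskConfig | None = None,
                         seed: int | None = None,
                         participant_id: str = "sim") -> TrialSchedule:
    """Build a counterbalanced scanner-session schedule.

    Every (context, coherence) cell occurs exactly ``reps_per_cell`` times,
    trials are split evenly across runs (each cell appearing equally often in
    every run when ``reps_per_cell`` divides ``n_runs``), and the order within
    a run is a seeded random permutation.  The correct direction of a
    0%-coherence trial is a fair coin flip.
    """
    config = config or TaskConfig()
    config.validate()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)

    cells = [(c, s) for c in range(config.n_contexts)
             for s in config.coherence_levels]
    per_run = _allocate_cells_to_runs(cells, config.reps_per_cell,
                                      config.n_runs, rng)

    frames = []
    trial_index = 1
    for r, run_cells in enumerate(per_run, start=1):
        order = rng.permutation(len(run_cells))
        run_cells = [run_cells[i] for i in order]
        n = len(run_cells)
        context = np.array([c for c, _ in run_cells], dtype=int)
        coherence = np.array([s for _, s in run_cells], dtype=float)
        correct = np.where(coherence > 0, UP,
                           np.where(coherence < 0, DOWN,
                                    rng.integers(0, 2, size=n)))
        itis, onset_cue, onset_stim, onset_fb = _timeline(n, config, rng)
        frames.append(pd.DataFrame({
            "participant_id": participant_id,
            "run": r,
            "trial_index": np.arange(trial_index, trial_index + n),
            "context": context,
            "coherence": coherence,
            "correct_direction": correct.astype(int),
            "onset_cue_s": onset_cue,
            "onset_stim_s": onset_stim,
            "onset_feedback_s": onset_fb,
            "iti_s": itis,
        }))
        trial_index += n
    return TrialSchedule(pd.concat(frames, ignore_index=True), config)


def practice_config() -> TaskConfig:
    """The laboratory practice-session design: 9 coherence levels x 60
    repetitions in six 90-trial blocks, no reward contexts."""
    return TaskConfig(n_contexts=1, coherence_levels=PRACTICE_COHERENCES,
                      reps_per_cell=60, n_runs=6,
                      high_reward_direction=(UP,), payoff_high=0.0,
                      payoff_low=0.0)


def build_practice_schedule(config: TaskConfig | None = None,
                            seed: int | None = None,
                            participant_id: str = "sim") -> TrialSchedule:
    """Build the practice schedule (540 trials, six 90-trial blocks).

    The returned table has no ``context`` column: practice trials carry no
    reward context or payoff.
    """
    config = config or practice_config()
    sched = build_trial_schedule(config, seed=seed, participant_id=participant_id)
    trials = sched.trials.drop(columns=["context"])
    return TrialSchedule(trials, config)


# --------------------------------------------------------------------------
# Payoff
# --------------------------------------------------------------------------

def assign_outcome(context: int, correct_direction: int, choice: int,
                   config: TaskConfig) -> float:
    """Reward points for a choice: high payoff for a correct choice in the
    context's high-reward direction, low payoff for a correct choice in the
    other direction, zero for an incorrect or omitted response."""
    if choice == NO_RESPONSE:
        return config.payoff_incorrect
    if choice not in (UP, DOWN):
        raise ValueError(f"unknown direction code {choice!r}")
    if not 0 <= context < config.n_contexts:
        raise ValueError(f"unknown context label {context!r}")
    if choice != correct_direction:
        return config.payoff_incorrect
    if choice == config.high_reward_direction[context]:
        return config.payoff_high
    return config.payoff_low
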