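"""Cohort-level maximum-likelihood fitting, AIC model comparison, and
parameter-recovery experiments.

Model comparison follows the group-AIC convention: each participant is fit
independently (3 free parameters per model), and the group score is

    AIC = sum over participants of (2 * NLL_n + 2k),   k = 3,

so the model with the lower group AIC wins; per-participant AICs give the
"N participants fit better" counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task
from .models import (CONTEXT_DEPENDENT, MODEL_KINDS,
                     ModelParams, RewardLearningModel, RewardLearningResults,
                     simulate_agent)

AIC_TIE_TOL = 1e-6


def fit_participant(data: pd.DataFrame, model_kind: str = CONTEXT_DEPENDENT,
                    q_init=None, n_starts: int = 10,
                    seed: int | None = 0) -> RewardLearningResults:
    """Fit one participant's trial table by multi-start Nelder-Mead ML."""
    model = RewardLearningModel(data, kind=model_kind, q_init=q_init)
    return model.fit(n_starts=n_starts, seed=seed)


def negative_log_likelihood(data: pd.DataFrame, params: ModelParams,
                            model_kind: str = CONTEXT_DEPENDENT,
                            q_init=None) -> float:
    """NLL of a trial table at fixed parameters (sum of -log P(chosen))."""
    return RewardLearningModel(data, kind=model_kind,
                               q_init=q_init).nloglike(params)


def fit_cohort(datasets: dict[str, pd.DataFrame] | list[pd.DataFrame],
               model_kind: str = CONTEXT_DEPENDENT, q_init=None,
               n_starts: int = 10, seed: int | None = 0,
               ) -> list[RewardLearningResults]:
    """Fit every participant under one model kind; per-participant fit seeds
    are derived from ``seed``."""
    if isinstance(datasets, dict):
        items = list(datasets.values())
    else:
        items = list(datasets)
    rng = np.random.default_rng(seed)
    fits = []
    for data in items:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fits.append(fit_participant(data, model_kind=model_kind,
                                    q_init=q_init, n_starts=n_starts,
                                    seed=sub_seed))
    return fits


def aic_group(fits: list[RewardLearningResults]) -> float:
    """Group AIC = sum_n (2 * nll_n + 2k)."""
    if not fits:
        raise ValueError("empty fit list")
    kinds = {f.model.kind for f in fits}
    if len(kinds) > 1:
        raise ValueError(f"fits mix model kinds: {sorted(kinds)}")
    return float(sum(f.aic for f in fits))


def fits_to_frame(fits: list[RewardLearningResults]) -> pd.DataFrame:
    """Tabulate fits (one row per participant x model)."""
    rows = []
    for f in fits:
        rows.append({
            "participant_id": f.model.participant_id,
            "model_kind": f.model.kind,
            "beta0": f.params.beta0,
            "beta1": f.params.beta1,
            "alpha": f.params.alpha,
            "nll": f.nll,
            "aic": f.aic,
            "converged": f.converged,
            "n_trials": f.nobs,
        })
    return pd.DataFrame(rows)


@dataclass
class CohortComparison:
    """Outcome of fitting the same cohort under several model kinds."""

    aic_by_model: dict[str, float]
    n_fit_better: dict[str, int]
    n_ties: int
    winner: str
    per_participant: pd.DataFrame
    fits: dict[str, list[RewardLearningResults]] = field(repr=False,
                                                         default_factory=dict)

    @property
    def n_participants(self) -> int:
        return self.per_participant["participant_id"].nunique()

    def to_json_dict(self) -> dict:
        return {
            "aic_by_model": self.aic_by_model,
            "n_fit_better": self.n_fit_better,
            "n_ties": self.n_ties,
            "winner": self.winner,
            "n_participants": self.n_participants,
        }

    def summary(self) -> str:
        lines = ["Model comparison (group AIC; lower is better)"]
        for kind, a in sorted(self.aic_by_model.items(), key=lambda kv: kv[1]):
            n = self.n_fit_better.get(kind, 0)
            lines.append(f"  {kind:<20} AIC {a:12.2f}   better for "
                         f"{n}/{self.n_participants} participants")
        if self.n_ties:
            lines.append(f"  unresolved ties: {self.n_ties}")
        lines.append(f"  winner: {self.winner}")
        return "\n".join(lines)


def compare_models(datasets: dict[str, pd.DataFrame] | list[pd.DataFrame],
                   model_kinds: tuple[str, ...] = MODEL_KINDS,
                   q_init=None, n_starts: int = 10,
                   seed: int | None = 0) -> CohortComparison:
    """Fit every dataset under every model kind and compare by AIC.

    The winner is the argmin of the group AIC; per-participant winners are
    counted from per-participant AICs, with |dAIC| < 1e-6 reported as
    unresolved ties rather than assigned to either model.
    """
    fits_by_kind: dict[str, list[RewardLearningResults]] = {}
    for kind in model_kinds:
        fits_by_kind[kind] = fit_cohort(datasets, model_kind=kind,
                                        q_init=q_init, n_starts=n_starts,
                                        seed=seed)
    n_each = {k: len(v) for k, v in fits_by_kind.items()}
    if len(set(n_each.values())) != 1:
        raise ValueError(f"mismatched participant sets across models: {n_each}")

    frames = [fits_to_frame(f) for f in fits_by_kind.values()]
    per_participant = pd.concat(frames, ignore_index=True)

    aic_by_model = {k: aic_group(v) for k, v in fits_by_kind.items()}
    n_fit_better = {k: 0 for k in model_kinds}
    n_ties = 0
    n = len(next(iter(fits_by_kind.values())))
    for i in range(n):
        aics = {k: fits_by_kind[k][i].aic for k in model_kinds}
        ordered = sorted(aics.items(), key=lambda kv: kv[1])
        if len(ordered) > 1 and ordered[1][1] - ordered[0][1] < AIC_TIE_TOL:
            n_ties += 1
        else:
            n_fit_better[ordered[0][0]] += 1
    winner = min(aic_by_model, key=aic_by_model.get)
    return CohortComparison(aic_by_model, n_fit_better, n_ties, winner,
                            per_participant, fits_by_kind)


# --------------------------------------------------------------------------
# Simulation harnesses
# --------------------------------------------------------------------------

def simulate_cohort(true_params: ModelParams,
                    model_kind: str = CONTEXT_DEPENDENT,
                    n_agents: int = 23,
                    config: task.TaskConfig | None = None,
                    seed: int | None = 0, q_init=None,
                    ) -> dict[str, pd.DataFrame]:
    """Simulate ``n_agents`` generative agents, each on its own seeded
    schedule, under one model kind."""
    config = config or task.TaskConfig()
    rng = np.random.default_rng(seed)
    cohort = {}
    for i in range(n_agents):
        pid = f"sim{i + 1:02d}"
        sched_seed, agent_seed = rng.integers(0, 2**31 - 1, size=2)
        sched = task.build_trial_schedule(config, seed=int(sched_seed),
                                          participant_id=pid)
        cohort[pid] = simulate_agent(sched, true_params, model_kind,
                                     q_init=q_init, seed=int(agent_seed))
    return cohort


def recover_parameters(true_params: ModelParams,
                       model_kind: str = CONTEXT_DEPENDENT,
                       n_agents: int = 23,
                       config: task.TaskConfig | None = None,
                       seed: int | None = 0, n_starts: int = 10,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit validation at known parameters.

    Returns ``(estimates, summary)``: per-agent estimates, and a
    per-parameter table with the truth, median/mean estimate, bias and RMSE.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    cohort = simulate_cohort(true_params, model_kind, n_agents, config, seed)
    fits = fit_cohort(cohort, model_kind=model_kind, n_starts=n_starts,
                      seed=seed)
    est = fits_to_frame(fits)
    est["participant_id"] = list(cohort.keys())
    truth = dict(zip(ModelParams.names, true_params.as_array()))
    rows = []
    for name in ModelParams.names:
        vals = est[name].to_numpy()
        rows.append({
            "param": name,
            "truth": truth[name],
            "median": float(np.median(vals)),
            "mean": float(np.mean(vals)),
            "bias": float(np.mean(vals) - truth[name]),
            "rmse": float(np.sqrt(np.mean((vals - truth[name]) ** 2))),
        })
    return est, pd.DataFrame(rows)
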