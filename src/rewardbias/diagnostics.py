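"""Behavioral diagnostics: psychometric summaries per run and context,
indecision-point trajectories, and residual autocorrelation checks.

Residual autocorrelations ask whether any trial-sequence structure (previous
choice, stimulus order, ...) remains after the learning model has absorbed
the context-reward association: residuals of the best-fit model should look
like white noise, i.e. stay inside the +/-1.96/sqrt(T) band of an
independent random series of the same length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

from . import task


@dataclass
class PsychometricSummary:
    """Choice proportions per (context, run, coherence) cell.

    ``cells``: per-participant per-cell table (n, p_up observed and, when a
    model trajectory was supplied, the model's mean predicted P(up)).
    ``group``: cell means +/- s.e.m. across participants.
    """

    cells: pd.DataFrame
    group: pd.DataFrame


def _stack(datasets) -> pd.DataFrame:
    if isinstance(datasets, dict):
        return pd.concat(datasets.values(), ignore_index=True)
    if isinstance(datasets, pd.DataFrame):
        return datasets
    return pd.concat(list(datasets), ignore_index=True)


def psychometric_by_run(datasets, trajectories=None) -> PsychometricSummary:
    """Observed P(up) per (context, run, coherence) cell, optionally paired
    with model-predicted probabilities averaged over the same cells.

    ``trajectories`` maps participant_id -> trajectory frame (from
    `RewardLearningResults.trajectory`), aligned trial-for-trial.
    """
    data = _stack(datasets).copy()
    data = data[data["choice"] != task.NO_RESPONSE]
    data["is_up"] = (data["choice"] == task.UP).astype(float)
    if trajectories is not None:
        p_model = []
        for pid, grp in data.groupby("participant_id", sort=False):
            traj = trajectories[pid]
            aligned = traj.set_index("trial_index")["p_up"]
            p_model.append(pd.Series(
                aligned.reindex(grp["trial_index"]).to_numpy(),
                index=grp.index))
        data["p_up_model"] = pd.concat(p_model)
    keys = ["participant_id", "context", "run", "coherence"]
    agg = {"is_up": ["size", "mean"]}
    if trajectories is not None:
        agg["p_up_model"] = ["mean"]
    cells = data.groupby(keys, observed=True).agg(
        n=("is_up", "size"), p_up_observed=("is_up", "mean"),
        **({"p_up_model": ("p_up_model", "mean")}
           if trajectories is not None else {}),
    ).reset_index()

    gkeys = ["context", "run", "coherence"]
    pieces = {"n": cells.groupby(gkeys)["n"].sum(),
              "p_up_observed": cells.groupby(gkeys)["p_up_observed"].mean(),
              "p_up_sem": cells.groupby(gkeys)["p_up_observed"].sem()}
    if trajectories is not None:
        pieces["p_up_model"] = cells.groupby(gkeys)["p_up_model"].mean()
    group = pd.DataFrame(pieces).reset_index()
    return PsychometricSummary(cells=cells, group=group)


@dataclass
class AcfReport:
    """Group-averaged residual autocorrelation function.

    ``band_halfwidth`` is the 95% white-noise band 1.96/sqrt(T) for a series
    of T trials; ``per_participant`` has one column per participant.
    """

    lags: np.ndarray
    acf_mean: np.ndarray
    per_participant: pd.DataFrame
    band_halfwidth: float
    n_trials: int

    def frac_outside_band(self, lag_min: int = 1) -> float:
        """Fraction of mean-ACF lags >= lag_min outside the white-noise band."""
        sel = self.lags >= lag_min
        return float(np.mean(np.abs(self.acf_mean[sel]) > self.band_halfwidth))


def residual_series(data: pd.DataFrame, trajectory: pd.DataFrame) -> np.ndarray:
    """Response residuals choice(0/1) - fitted P(up), ordered by trial."""
    ch = trajectory["choice"].to_numpy().astype(float)
    ch[ch == task.NO_RESPONSE] = np.nan
    return ch - trajectory["p_up"].to_numpy()


def residual_acf(datasets, trajectories, max_lag: int = 20) -> AcfReport:
    """Sample ACF of model residuals per participant, averaged with equal
    weights across participants.

    Each participant's residual series is mean-centered and normalized by
    its lag-0 autocovariance (the standard sample ACF).  The white-noise
    band uses T = trials per participant.
    """
    if isinstance(trajectories, pd.DataFrame):
        trajectories = {"p1": trajectories}
    cols = {}
    n_trials = None
    for pid, traj in trajectories.items():
        resid = traj["choice"].to_numpy().astype(float) - traj["p_up"].to_numpy()
        T = resid.size
        if max_lag >= T:
            raise ValueError(f"max_lag {max_lag} >= series length {T}")
        n_trials = T if n_trials is None else n_trials
        cols[pid] = _sm_acf(resid, nlags=max_lag, fft=False)
    per = pd.DataFrame(cols, index=pd.RangeIndex(max_lag + 1, name="lag"))
    return AcfReport(lags=np.arange(max_lag + 1),
                     acf_mean=per.mean(axis=1).to_numpy(),
                     per_participant=per,
                     band_halfwidth=1.96 / np.sqrt(n_trials),
                     n_trials=n_trials)


@dataclass
class IndecisionTrajectorySummary:
    """Group mean +/- s.e.m. of per-trial indecision points per context."""

    table: pd.DataFrame  # columns: trial_index, context, mean, sem
    run_boundaries: list[int]
    single_participant: bool


def indecision_trajectory_summary(trajectories) -> IndecisionTrajectorySummary:
    """Per-trial group mean and s.e.m. of the indecision points of both
    contexts (evaluated at every trial's pre-choice values).

    With a single participant the s.e.m. is undefined and flagged.
    """
    if isinstance(trajectories, pd.DataFrame):
        trajectories = {"p1": trajectories}
    trajs = list(trajectories.values())
    lengths = {len(t) for t in trajs}
    if len(lengths) != 1:
        raise ValueError("participants have unequal trial counts")
    single = len(trajs) == 1
    rows = []
    for ctx, col in ((0, "ip_context0"), (1, "ip_context1")):
        mat = np.column_stack([t[col].to_numpy() for t in trajs])
        mean = mat.mean(axis=1)
        sem = (np.full(mat.shape[0], np.nan) if single
               else mat.std(axis=1, ddof=1) / np.sqrt(mat.shape[1]))
        rows.append(pd.DataFrame({
            "trial_index": trajs[0]["trial_index"].to_numpy(),
            "context": ctx, "mean": mean, "sem": sem,
        }))
    runs = trajs[0].groupby("run")["trial_index"].max().tolist()
    return IndecisionTrajectorySummary(pd.concat(rows, ignore_index=True),
                                       run_boundaries=runs,
                                       single_participant=single)
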