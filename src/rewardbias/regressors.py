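"""Model-derived fMRI parametric modulators as FSL three-column event files.

Each modulated regressor attaches a trial-wise scalar to an event window:

    abs_coherence     |S_t|                stimulus onset -> offset (0.2 s)
    bias_amount       |Q(up|c) - Q(down|c)| cue onset -> stimulus offset
    rpe_contextual    delta'_t              feedback onset -> offset (1.5 s)
    rpe_context_free  delta_t               feedback onset -> offset
    rpe_unsigned      |delta'_t|            feedback onset -> offset

Weights are mean-centered within run (the first-level GLMs are estimated per
run); whole-session centering is available.  An unmodulated trial-evoked
boxcar (weight 1, cue onset -> feedback offset) and, when reaction times are
recorded, a response boxcar are exported alongside.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import task

MODULATORS = ("abs_coherence", "bias_amount", "rpe_contextual",
              "rpe_context_free", "rpe_unsigned")


def _modulator_values(data: pd.DataFrame, trajectory: pd.DataFrame,
                      which: str) -> np.ndarray:
    if which == "abs_coherence":
        return np.abs(data["coherence"].to_numpy())
    if which == "bias_amount":
        return trajectory["bias_amount"].to_numpy()
    if which in ("rpe_contextual", "rpe_context_free"):
        return trajectory["rpe"].to_numpy()
    if which == "rpe_unsigned":
        return np.abs(trajectory["rpe"].to_numpy())
    raise ValueError(f"unknown modulator {which!r}")


def _event_window(data: pd.DataFrame, config: task.TaskConfig,
                  which: str) -> tuple[np.ndarray, float]:
    if which == "abs_coherence":
        return data["onset_stim_s"].to_numpy(), config.stim_duration_s
    if which == "bias_amount":
        return (data["onset_cue_s"].to_numpy(),
                config.cue_duration_s + config.stim_duration_s)
    return data["onset_feedback_s"].to_numpy(), config.feedback_duration_s


def build_modulator_series(data: pd.DataFrame, trajectory: pd.DataFrame,
                           which: str,
                           config: task.TaskConfig | None = None,
                           center: str = "run",
                           ) -> dict[int, pd.DataFrame]:
    """Per-run (onset, duration, weight) tables for one parametric modulator.

    ``trajectory`` must come from the model fitted to ``data`` (same trial
    order).  ``center`` is "run" (default) or "session".
    """
    if which not in MODULATORS:
        raise ValueError(f"unknown modulator {which!r}; "
                         f"choose from {MODULATORS}")
    if center not in ("run", "session"):
        raise ValueError("center must be 'run' or 'session'")
    if len(trajectory) != len(data):
        raise ValueError("trajectory and dataset have different lengths")
    config = config or task.TaskConfig()
    values = _modulator_values(data, trajectory, which).astype(float)
    onsets, duration = _event_window(data, config, which)
    runs = data["run"].to_numpy()
    if center == "session":
        values = values - np.nanmean(values)
    out = {}
    for r in np.unique(runs):
        mask = runs == r
        w = values[mask]
        if center == "run":
            w = w - np.nanmean(w)
        out[int(r)] = pd.DataFrame({
            "onset": onsets[mask], "duration": duration, "weight": w,
        })
    return out


def trial_boxcar_series(data: pd.DataFrame,
                        config: task.TaskConfig | None = None,
                        ) -> dict[int, pd.DataFrame]:
    """Unmodulated trial-evoked boxcar: weight 1 from cue onset to feedback
    offset (the start of the next ITI)."""
    config = config or task.TaskConfig()
    out = {}
    for r, grp in data.groupby("run"):
        onset = grp["onset_cue_s"].to_numpy()
        dur = (grp["onset_feedback_s"].to_numpy()
               + config.feedback_duration_s - onset)
        out[int(r)] = pd.DataFrame({"onset": onset, "duration": dur,
                                    "weight": 1.0})
    return out


def response_boxcar_series(data: pd.DataFrame) -> dict[int, pd.DataFrame] | None:
    """Response boxcar (stimulus onset -> key press); None without an
    ``rt_s`` column, since the package does not model reaction times."""
    if "rt_s" not in data.columns:
        return None
    out = {}
    for r, grp in data.groupby("run"):
        resp = grp[grp["choice"] != task.NO_RESPONSE]
        out[int(r)] = pd.DataFrame({
            "onset": resp["onset_stim_s"].to_numpy(),
            "duration": resp["rt_s"].to_numpy(),
            "weight": 1.0,
        })
    return out


def write_three_column(events: pd.DataFrame, path: Path) -> None:
    """Write an FSL custom-timing EV file (onset duration weight, %.6f)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for row in events.itertuples(index=False):
            fh.write(f"{row.onset:.6f}\t{row.duration:.6f}\t{row.weight:.6f}\n")


def read_three_column(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["onset", "duration", "weight"])


def export_fsl_events(data: pd.DataFrame, trajectory: pd.DataFrame,
                      directory: Path,
                      config: task.TaskConfig | None = None,
                      regressors: tuple[str, ...] = MODULATORS,
                      center: str = "run",
                      participant_id: str | None = None) -> dict:
    """Write one three-column EV file per (run, regressor) plus the
    trial-evoked boxcar (and a response boxcar when RTs exist); returns the
    manifest, which is also saved as ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = config or task.TaskConfig()
    pid = participant_id or str(data["participant_id"].iloc[0])
    series = {name: build_modulator_series(data, trajectory, name, config,
                                           center=center)
              for name in regressors}
    series["trial_boxcar"] = trial_boxcar_series(data, config)
    resp = response_boxcar_series(data)
    if resp is not None:
        series["response_boxcar"] = resp
    manifest = {"participant_id": pid, "center": center, "files": {}}
    for name, by_run in series.items():
        manifest["files"][name] = {}
        for r, events in by_run.items():
            fname = f"{pid}_run{r}_{name}.txt"
            write_three_column(events, directory / fname)
            manifest["files"][name][str(r)] = fname
    with open(directory / f"{pid}_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
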