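"""Reading and writing trial tables, fit tables and configs.

Trial tables are UTF-8 tab-separated files, one row per trial, with the
fixed header defined in `task.TRIAL_COLUMNS` plus the behavioral columns
(choice, correct, reward) once an agent or participant has responded.
Task configuration round-trips through TOML.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import pandas as pd

from .task import TaskConfig

_FLOAT_FMT = "%.6f"


def write_trials(data: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trials(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fit_table(table: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=str)


def task_config_from_toml(path: Path) -> TaskConfig:
    """Build a TaskConfig from a TOML file whose keys mirror its fields
    (a ``[task]`` table is honoured if present)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw = raw.get("task", raw)
    fields = {f.name for f in dataclasses.fields(TaskConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown TaskConfig keys in {path}: {sorted(unknown)}")
    for key in ("coherence_levels", "high_reward_direction"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return TaskConfig(**raw)


def task_config_to_toml_str(config: TaskConfig) -> str:
    lines = ["[task]"]
    for f in dataclasses.fields(TaskConfig):
        val = getattr(config, f.name)
        if val is None:
            continue
        if isinstance(val, tuple):
            lines.append(f"{f.name} = {list(val)}")
        elif isinstance(val, str):
            lines.append(f'{f.name} = "{val}"')
        else:
            lines.append(f"{f.name} = {val}")
    return "\n".join(lines) + "\n"
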