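"""CSV dataset and JSON configuration round-tripping.

Dataset CSV schema (one row per trial, header mandatory, UTF-8, sorted by
(participant_id, run, trial)):

``participant_id, run, trial, s2, action, reward, observation, valid``
plus an optional ``s1`` column present only for synthetic data.  Invalid
trials (missed responses) have empty action/reward/observation and
``valid = 0``.  Action/observation pairs are checked against the task's
observation function on load and save.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .simulate import DATASET_COLUMNS, ChoiceDataset
from .task import TaskConfig, observation_function

__all__ = [
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "load_task_config",
    "dump_task_config",
    "config_hash",
]


class DatasetFormatError(ValueError):
    """Raised for malformed or inconsistent dataset files."""


def _check_rows(df: pd.DataFrame, path: Path | str) -> None:
    required = [c for c in DATASET_COLUMNS if c != "s1"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise DatasetFormatError(f"{path}: empty dataset")
    sort_keys = df[["participant_id", "run", "trial"]]
    if not sort_keys.equals(sort_keys.sort_values(["participant_id", "run", "trial"])):
        raise DatasetFormatError(f"{path}: rows are not sorted by (participant, run, trial)")
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        if int(row["valid"]) not in (0, 1):
            raise DatasetFormatError(f"{path} row {rowno}: valid must be 0 or 1")
        if int(row["s2"]) not in (1, 2):
            raise DatasetFormatError(f"{path} row {rowno}: s2 must be 1 or 2")
        if int(row["valid"]) == 0:
            if not (
                pd.isna(row["action"]) and pd.isna(row["reward"]) and pd.isna(row["observation"])
            ):
                raise DatasetFormatError(
                    f"{path} row {rowno}: invalid trials must have empty action/reward/observation"
                )
            continue
        try:
            action, reward, obs = int(row["action"]), int(row["reward"]), int(row["observation"])
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(f"{path} row {rowno}: non-integer trial fields") from exc
        expected = observation_function(action, reward)
        if obs != expected:
            raise DatasetFormatError(
                f"{path} row {rowno}: observation {obs} inconsistent with "
                f"action {action} and reward {reward} (expected {expected})"
            )
        available = {1, 4} if int(row["s2"]) == 1 else {2, 3}
        if action not in available:
            raise DatasetFormatError(
                f"{path} row {rowno}: action {action} unavailable under s2={row['s2']}"
            )


def read_dataset(path: str | Path) -> list[ChoiceDataset]:
    """Read a dataset CSV; returns one ChoiceDataset per participant."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise DatasetFormatError(f"{path}: empty dataset file") from exc
    _check_rows(df, path)
    meta_path = path.with_suffix(".json")
    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    out = []
    for pid, chunk in df.groupby("participant_id", sort=True):
        chunk = chunk.reset_index(drop=True)
        for col in ("action", "reward", "observation"):
            chunk[col] = chunk[col].astype("Int64")
        out.append(ChoiceDataset(trials=chunk, meta=dict(meta, participant_id=pid)))
    return out


def write_dataset(
    datasets: ChoiceDataset | list[ChoiceDataset], path: str | Path
) -> None:
    """Write one or more ChoiceDatasets to a CSV plus a JSON metadata sidecar."""
    if isinstance(datasets, ChoiceDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        df = ds.trials.copy()
        for col in ("action", "reward", "observation"):
            df[col] = df[col].astype("Int64")
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    cols = [c for c in DATASET_COLUMNS if c in combined.columns]
    combined = combined[cols].sort_values(["participant_id", "run", "trial"])
    _check_rows(combined.reset_index(drop=True), path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    combined.to_csv(path, index=False)
    meta = {k: v for k, v in datasets[0].meta.items() if k != "participant_id"}
    if meta:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_task_config(path: str | Path) -> TaskConfig:
    """Load a TaskConfig from JSON; unknown keys are rejected."""
    raw = json.loads(Path(path).read_text())
    known = set(TaskConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise DatasetFormatError(f"unknown task config keys: {sorted(unknown)}")
    return TaskConfig(**raw)


def dump_task_config(config: TaskConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2))


def config_hash(config: TaskConfig) -> str:
    """Stable short hash of a task configuration, for logging."""
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
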