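"""Readers and writers for trial logs and task configurations.

Trial logs travel as plain CSV (comma-separated, header row, UTF-8) with
one row per trial and columns ``subject,game,trial,phase,action,transition,
second_state,reward,devalued_game``.  Hidden rewards are written as an
empty field; the ``trial`` column is 1-based on disk and 0-based in
memory.  Reading is strict: schema violations raise with the offending
line number.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import TRIAL_COLUMNS
from .task import PHASES, TaskConfig

_VALID_ACTIONS = {"left", "right", "none"}
_VALID_TRANSITIONS = {"common", "rare", "none"}


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial log to CSV (1-based trial, hidden rewards empty)."""
    out = trials[TRIAL_COLUMNS].copy()
    out["trial"] = out["trial"].astype(int) + 1

    def fmt_reward(r):
        if r is None or (isinstance(r, float) and math.isnan(r)):
            return ""
        return str(int(r))

    out["reward"] = out["reward"].map(fmt_reward)
    out["devalued_game"] = out["devalued_game"].map(lambda b: str(bool(b)))
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV written by :func:`write_trials`.

    Raises ``ValueError`` naming the first offending line (line 1 is the
    header) for unknown labels or out-of-range rewards; an empty file is a
    structured "no trials" error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: no trials (empty file)")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != TRIAL_COLUMNS:
        raise ValueError(f"{path}: expected columns {TRIAL_COLUMNS}, "
                         f"got {list(df.columns)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no trials (header only)")

    def bad(i: int, msg: str):
        return ValueError(f"{path}, line {i + 2}: {msg}")

    rewards = np.full(len(df), math.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.phase not in PHASES:
            raise bad(i, f"unknown phase {row.phase!r}")
        if row.action not in _VALID_ACTIONS:
            raise bad(i, f"unknown action {row.action!r}")
        if row.transition not in _VALID_TRANSITIONS:
            raise bad(i, f"unknown transition {row.transition!r}")
        if not row.trial.isdigit() or int(row.trial) < 1:
            raise bad(i, f"trial must be a positive integer, got {row.trial!r}")
        if row.reward == "":
            continue
        try:
            r = int(row.reward)
        except ValueError:
            raise bad(i, f"reward must be an integer or empty, "
                         f"got {row.reward!r}") from None
        hi = 10 if row.phase == "consumption" else 1
        if not 0 <= r <= hi:
            raise bad(i, f"reward {r} out of range 0..{hi} "
                         f"for phase {row.phase}")
        rewards[i] = float(r)

    out = pd.DataFrame({
        "subject": df["subject"],
        "game": df["game"],
        "trial": df["trial"].astype(int) - 1,
        "phase": df["phase"],
        "action": df["action"],
        "transition": df["transition"],
        "second_state": df["second_state"],
        "reward": rewards,
        "devalued_game": df["devalued_game"].map(
            {"True": True, "False": False}),
    })
    if out["devalued_game"].isna().any():
        i = int(out["devalued_game"].isna().idxmax())
        raise bad(i, "devalued_game must be True or False")
    return out


def write_config(config: TaskConfig, path) -> None:
    Path(path).write_text(config.to_json(), encoding="utf-8")


def read_config(path) -> TaskConfig:
    return TaskConfig.from_json(Path(path).read_text(encoding="utf-8"))
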