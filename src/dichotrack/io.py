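"""Reading and writing the long-format trace/trial tables.

One tabular dialect is used throughout: comma-separated, '.' decimal,
UTF-8, one row per sample, with columns

    trial_id, t, c_left, c_right, phase, fast_eye, dropout_eye,
    dropout_cycle_index [, j]

The ``j`` column (joystick position) is present for observer datasets
and absent for pure stimulus schedules. Files include a
``schema_version`` comment on the first line. Round-trips are lossless
to well below 1e-9; schema violations are reported with row numbers
and no silent resampling or interpolation is performed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .observer import JoystickTrace
from .stimulus import TrialSet, TrialTimecourse

__all__ = ["write_trials", "write_traces", "read_trials", "read_traces"]

SCHEMA_VERSION = 1

_TRIAL_COLUMNS = [
    "trial_id",
    "t",
    "c_left",
    "c_right",
    "phase",
    "fast_eye",
    "dropout_eye",
    "dropout_cycle_index",
]


def _trial_frame(trial_set: TrialSet) -> pd.DataFrame:
    frames = []
    for trial in trial_set:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": trial.trial_id,
                    "t": trial.t,
                    "c_left": trial.c_left,
                    "c_right": trial.c_right,
                    "phase": trial.phase,
                    "fast_eye": trial.fast_eye,
                    "dropout_eye": trial.dropout_eye,
                    "dropout_cycle_index": trial.dropout_cycle_index,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _write(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# dichotrack schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def write_trials(trial_set: TrialSet, path: str | Path) -> None:
    """Write a stimulus schedule (no joystick column)."""
    _write(_trial_frame(trial_set), path)


def write_traces(
    trial_set: TrialSet, traces: list[JoystickTrace], path: str | Path
) -> None:
    """Write an observer dataset (stimulus schedule plus ``j``)."""
    df = _trial_frame(trial_set)
    df["j"] = np.concatenate([tr.j for tr in traces])
    _write(df, path)


def _read_frame(path: str | Path, require_j: bool) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = _TRIAL_COLUMNS + (["j"] if require_j else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = df.index[
        (df["c_left"] < 0) | (df["c_left"] > 1) | (df["c_right"] < 0) | (df["c_right"] > 1)
    ]
    if len(bad):
        raise FormatError(
            f"{path}: contrast outside [0, 1] at row(s) {list(bad[:5] + 2)}"
        )
    return df


def _rebuild(df: pd.DataFrame, with_traces: bool):
    trials, traces = [], []
    for tid, g in df.groupby("trial_id", sort=True):
        t = g["t"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            row = int(g.index[np.argmax(np.diff(t) <= 0)]) + 2
            raise FormatError(f"non-monotone t within trial {tid} near row {row}")
        dt = np.diff(t)
        if len(dt) and np.max(np.abs(dt - dt[0])) > 1e-6:
            raise FormatError(
                f"trial {tid}: time grid has gaps; resampling is refused"
            )
        rate = 1.0 / dt[0] if len(dt) else 1.0
        trials.append(
            TrialTimecourse(
                sample_rate=float(round(rate, 9)),
                t=t,
                c_left=g["c_left"].to_numpy(float),
                c_right=g["c_right"].to_numpy(float),
                phase=g["phase"].to_numpy(str),
                fast_eye=str(g["fast_eye"].iloc[0]),
                dropout_eye=str(g["dropout_eye"].iloc[0]),
                dropout_cycle_index=int(g["dropout_cycle_index"].iloc[0]),
                trial_id=int(tid),
            )
        )
        if with_traces:
            traces.append(
                JoystickTrace(trial_id=int(tid), t=t, j=g["j"].to_numpy(float))
            )
    trial_set = TrialSet(trials=trials)
    return (trial_set, traces) if with_traces else trial_set


def read_trials(path: str | Path) -> TrialSet:
    """Read a stimulus schedule written by :func:`write_trials`."""
    return _rebuild(_read_frame(path, require_j=False), with_traces=False)


def read_traces(path: str | Path) -> tuple[TrialSet, list[JoystickTrace]]:
    """Read an observer dataset written by :func:`write_traces`."""
    return _rebuild(_read_frame(path, require_j=True), with_traces=True)
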