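"""Plain-text I/O for trial records, rate traces and spike events."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "write_trial_records",
    "read_trial_records",
    "write_rate_trace",
    "read_rate_trace",
    "write_spikes",
    "read_spikes",
]

#: Canonical column order of the trial-record CSV dialect.
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "condition",
    "trial_index",
    "coherence_signed",
    "direction",
    "choice",
    "responded",
    "decision_time_s",
    "prestim_rate_chosen_hz",
    "prestim_rate_unchosen_hz",
    "previous_choice",
]


def write_trial_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in the canonical CSV dialect (extra columns kept)."""
    cols = [c for c in TRIAL_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records[cols].to_csv(path, index=False)


def read_trial_records(path: str | Path) -> pd.DataFrame:
    """Read a trial-record CSV, validating the required columns."""
    df = pd.read_csv(path)
    missing = [
        c
        for c in ("subject_id", "coherence_signed", "choice", "previous_choice")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"trial-record file {path} lacks columns: {missing}")
    for col in ("choice", "previous_choice"):
        df[col] = df[col].fillna("none").astype(str)
    return df


def write_rate_trace(times_ms, rates_hz, path: str | Path, population: str = "") -> None:
    """Two-column CSV (time_ms, rate_hz) with a header row."""
    df = pd.DataFrame({"time_ms": times_ms, "rate_hz": rates_hz})
    if population:
        df["population"] = population
    df.to_csv(path, index=False)


def read_rate_trace(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_ms", "rate_hz"} <= set(df.columns):
        raise ValueError(f"{path} is not a rate-trace CSV")
    return df


def write_spikes(neuron_ids, times_ms, path: str | Path) -> None:
    """Two-column whitespace text: neuron id, spike time in ms."""
    arr = np.column_stack([np.asarray(neuron_ids), np.asarray(times_ms)])
    np.savetxt(path, arr, fmt=["%d", "%.3f"])


def read_spikes(path: str | Path):
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return np.array([], dtype=int), np.array([])
    return arr[:, 0].astype(int), arr[:, 1]
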