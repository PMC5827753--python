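"""Readers and writers for the pipeline's delimited formats.

EEG comes in either as an EDF file (via :mod:`mne`, optional extra) or as a
delimited numeric table with channels as columns and a header row of channel
names; sampling rate from the EDF header or the caller. Artifact masks are
serialized as per-channel run-length JSON so cleaned recordings round-trip
through plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import CHANNELS_20
from .recording import EEGRecording


def read_eeg_table(path, fs: float, sep: str = ",") -> EEGRecording:
    """Read a delimited EEG table (channels as columns, header of names)."""
    table = pd.read_csv(path, sep=sep)
    if table.empty:
        raise ValueError(f"empty EEG table: {path}")
    return EEGRecording(
        samples=table.to_numpy(dtype=float).T,
        fs=fs,
        channel_names=tuple(str(c) for c in table.columns),
    )


def write_eeg_table(recording: EEGRecording, path, sep: str = ",") -> None:
    pd.DataFrame(recording.samples.T, columns=recording.channel_names).to_csv(
        path, sep=sep, index=False
    )


def read_edf(path, channels: tuple[str, ...] = CHANNELS_20) -> EEGRecording:
    """Read an EDF recording; channel labels are matched order-insensitively."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("EDF reading requires the 'edf' extra (mne)") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    present = [ch for ch in channels if ch in raw.ch_names]
    missing = set(channels) - set(present)
    if missing:
        raise ValueError(f"EDF is missing expected channels: {sorted(missing)}")
    raw.pick(present)
    return EEGRecording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(present),
    )


# ---------------------------------------------------------------------------
# run-length mask serialization
# ---------------------------------------------------------------------------

def mask_to_runs(mask: np.ndarray, channel_names) -> dict[str, list[list[int]]]:
    """Per-channel [start, stop) runs of True in a channels × time mask."""
    mask = np.asarray(mask, dtype=bool)
    out: dict[str, list[list[int]]] = {}
    for name, row in zip(channel_names, mask):
        padded = np.concatenate(([False], row, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        stops = np.flatnonzero(diff == -1)
        out[str(name)] = [[int(s), int(e)] for s, e in zip(starts, stops)]
    return out


def runs_to_mask(runs: dict[str, list[list[int]]], channel_names, n_samples: int) -> np.ndarray:
    mask = np.zeros((len(channel_names), n_samples), dtype=bool)
    for i, name in enumerate(channel_names):
        for start, stop in runs.get(str(name), []):
            mask[i, start:stop] = True
    return mask


def write_mask_json(mask: np.ndarray, channel_names, path) -> None:
    Path(path).write_text(json.dumps(mask_to_runs(mask, channel_names)))


def read_mask_json(path, channel_names, n_samples: int) -> np.ndarray:
    return runs_to_mask(json.loads(Path(path).read_text()), channel_names, n_samples)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited feature table (one row per recording)."""
    return pd.read_csv(path, sep=sep)


def write_feature_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False)
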