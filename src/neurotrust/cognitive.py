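"""Closed-form cognitive EEG features.

Five features are computed from a preprocessed recording and its windowed
PSD: per-system mental load (ML), situation awareness (SA), blink rate (BR),
the frontal alpha asymmetry index (AI) and completion time (CT). Two further
slots — mental workload (MW) and engagement (E), both probabilities in
[0, 1] — come from external proprietary classifiers and are accepted as
pass-through inputs only, never computed here.

Conventions (the aggregation is otherwise underdetermined):

* a channel's "total power amplitude" A(j) is the time-average over retained
  windows of its full-band integrated PSD; ML of a system sums A(j) over the
  system's channels;
* SA averages band-integrated frontal power over channels, then windows, for
  the theta and gamma bands and adds the two;
* AI uses the per-window alpha-power series of F3/F7 (left) and F4/F8
  (right), 3-SD-cleaned, and compares the (max − min) dynamic ranges:
  AI = (L − R)/(L + R), negative when the right hemisphere's alpha range
  dominates (a negative-emotion marker).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import ALPHA, GAMMA, THETA
from .parcellation import DEFAULT_PARCELLATION, SystemParcellation
from .preprocessing import PSDSpectrogram, remove_outliers
from .recording import EEGRecording

#: Channels entering the asymmetry index: (left, right) frontal pairs.
AI_PAIRS = (("F3", "F4"), ("F7", "F8"))


@dataclass
class CognitiveFeatures:
    """The 12 cognitive feature slots for one recording.

    MW and E are optional externally supplied probabilities; absent values
    stay None and must be excluded from any active feature subset downstream.
    """

    ML: dict[str, float]
    SA: float
    BR: float
    AI: float
    CT: float
    MW: float | None = None
    E: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.BR <= 1:
            raise ValueError("BR must lie in [0, 1]")
        if not -1 <= self.AI <= 1:
            raise ValueError("AI must lie in [-1, 1]")
        if self.CT <= 0:
            raise ValueError("CT must be positive")
        if self.SA < 0 or any(v < 0 for v in self.ML.values()):
            raise ValueError("ML and SA are power quantities and must be >= 0")
        for name, v in (("MW", self.MW), ("E", self.E)):
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1] when supplied")

    def as_row(self) -> dict[str, float | None]:
        """Flatten into the canonical cognitive feature columns."""
        row: dict[str, float | None] = {"MW": self.MW}
        for sys in ("F", "PF", "C", "T", "Pa", "O"):
            row[f"ML_{sys}"] = self.ML.get(sys)
        row.update(SA=self.SA, E=self.E, BR=self.BR, AI=self.AI, CT=self.CT)
        return row


def mental_load(
    spectrogram: PSDSpectrogram,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
    system: str = "F",
) -> float:
    """ML_i = Σ_{j ∈ system i} A(j): summed time-averaged total power."""
    channels = [ch for ch in parcellation.channels(system) if ch in spectrogram.channel_names]
    if not channels:
        raise ValueError(f"no channels of system {system!r} present in spectrogram")
    total = spectrogram.total_power()  # channel × window
    idx = [spectrogram.channel_index(ch) for ch in channels]
    per_channel = np.nanmean(total[idx], axis=1)
    if np.isnan(per_channel).any():
        raise ValueError("a channel has no retained PSD windows")
    return float(per_channel.sum())


def situation_awareness(
    spectrogram: PSDSpectrogram,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
) -> float:
    """SA = frontal θ-band power + frontal γ-band power (channel/window mean)."""
    channels = [ch for ch in parcellation.channels("F") if ch in spectrogram.channel_names]
    if not channels:
        raise ValueError("no frontal channels present")
    idx = [spectrogram.channel_index(ch) for ch in channels]
    out = 0.0
    for band in (THETA, GAMMA):
        bp = spectrogram.band_power(band)[idx]
        val = np.nanmean(bp)
        if np.isnan(val):
            raise ValueError("no retained PSD windows on the frontal channels")
        out += float(val)
    return out


def blink_rate(mask: np.ndarray) -> float:
    """BR = N_c / N: fraction of time points marked as blink-contaminated.

    Accepts either a time mask (1-D) or a channels × time mask, in which case
    a time point counts as contaminated when any channel marks it.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    if mask.ndim == 2:
        mask = mask.any(axis=0)
    elif mask.ndim != 1:
        raise ValueError("mask must be 1-D or 2-D")
    return float(mask.sum() / mask.size)


def _alpha_range(spectrogram: PSDSpectrogram, channel: str) -> float:
    series = spectrogram.band_power(ALPHA)[spectrogram.channel_index(channel)]
    series = series[~np.isnan(series)]
    if series.size < 2:
        raise ValueError(f"too few retained windows on channel {channel}")
    cleaned, _ = remove_outliers(series)
    return float(cleaned.max() - cleaned.min())


def asymmetry_index(spectrogram: PSDSpectrogram) -> float:
    """Frontal alpha asymmetry: AI = (L − R)/(L + R).

    L and R sum the outlier-cleaned per-window alpha-power ranges of the
    left (F3, F7) and right (F4, F8) frontal channels. Mirror-symmetric
    signals give 0; swapping hemispheres flips the sign. A flat recording
    (L + R = 0) is degenerate and raises.
    """
    for left, right in AI_PAIRS:
        for ch in (left, right):
            if ch not in spectrogram.channel_names:
                raise ValueError(f"channel {ch} required for the asymmetry index")
    L = sum(_alpha_range(spectrogram, left) for left, _ in AI_PAIRS)
    R = sum(_alpha_range(spectrogram, right) for _, right in AI_PAIRS)
    if L + R == 0:
        raise ValueError("degenerate (flat) input: zero alpha-power range on both sides")
    return float((L - R) / (L + R))


def completion_time(recording: EEGRecording) -> float:
    """CT = N / f_s, the recording duration in seconds."""
    return recording.duration


def cognitive_features(
    recording: EEGRecording,
    spectrogram: PSDSpectrogram,
    blink_mask: np.ndarray,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
    MW: float | None = None,
    E: float | None = None,
) -> CognitiveFeatures:
    """Assemble all cognitive features for one recording."""
    ML = {
        sys: mental_load(spectrogram, parcellation, sys)
        for sys in parcellation.system_names
    }
    return CognitiveFeatures(
        ML=ML,
        SA=situation_awareness(spectrogram, parcellation),
        BR=blink_rate(blink_mask),
        AI=asymmetry_index(spectrogram),
        CT=completion_time(recording),
        MW=MW,
        E=E,
    )
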