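"""Multichannel EEG container.

Amplitudes are kept in the recording's native units throughout; artifact
handling never modifies sample values, it only marks them in a boolean mask
aligned with the samples. All downstream exclusion happens through the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """Channels × time EEG with sampling rate, channel names and artifact mask.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitude in native units.
    fs : float
        Sampling rate in Hz (default 256).
    channel_names : sequence of str
        Unique ordered channel labels, one per row of ``samples``.
    artifact_mask : ndarray of bool, same shape as ``samples``, optional
        True marks contaminated samples. Defaults to all-False.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty channels × time matrix")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("one channel name required per samples row")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.shape, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.samples.shape:
                raise ValueError("artifact_mask must have the same shape as samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (N / fs)."""
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        """Copy of the recording with replaced sample values (mask preserved)."""
        return EEGRecording(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            channel_names=self.channel_names,
            artifact_mask=self.artifact_mask.copy(),
        )

    def with_mask(self, mask: np.ndarray, combine: bool = True) -> "EEGRecording":
        """Copy with an updated artifact mask.

        With ``combine=True`` (default) the new mask is OR-ed into the
        existing one, so successively detected artifact classes accumulate.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.samples.shape:
            raise ValueError("mask shape mismatch")
        new_mask = (self.artifact_mask | mask) if combine else mask
        return EEGRecording(
            samples=self.samples.copy(),
            fs=self.fs,
            channel_names=self.channel_names,
            artifact_mask=new_mask,
        )

    def copy(self) -> "EEGRecording":
        return self.with_samples(self.samples.copy())
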