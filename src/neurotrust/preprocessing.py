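"""EEG cleaning and spectral estimation.

The cleaning chain mirrors standard intraoperative-EEG practice: mark
short high-amplitude excursion runs (saturation spikes), notch out mains
interference, band-pass to the analysis band, mark blink-contaminated
stretches on the frontal channels, then estimate windowed power spectral
densities with a Kaiser taper. Artifact detection only ever *marks*
samples; values are excluded downstream via the mask, never edited.

All filters are applied forward-backward (zero phase) so that instantaneous
phase estimates computed later are not biased by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BandDefinition
from .recording import EEGRecording

#: Default Kaiser shape parameter for the PSD taper (Blackman-like sidelobes).
KAISER_BETA = 8.6

#: Default spike run lengths and amplitude threshold (native units).
SPIKE_RUN_LENGTHS = frozenset({3, 5, 7})
SPIKE_AMPLITUDE = 40.0

#: Default frontal channels used by the blink detector.
BLINK_CHANNELS = ("Fp1", "Fp2", "F3", "F4")

#: Windows with more than this fraction of masked samples are dropped.
WINDOW_REJECT_FRACTION = 0.25


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------

def _runs(mask_1d: np.ndarray):
    """Yield (start, length) of each maximal run of True in a boolean vector."""
    padded = np.concatenate(([False], mask_1d, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e - s)


def detect_spike_artifacts(
    recording: EEGRecording,
    run_lengths: frozenset[int] | set[int] = SPIKE_RUN_LENGTHS,
    amp_threshold: float = SPIKE_AMPLITUDE,
) -> np.ndarray:
    """Mask saturation/excursion spikes: runs of supra-threshold samples.

    A run of consecutive samples with ``|x| > amp_threshold`` is masked when
    its length is in ``run_lengths`` (default {3, 5, 7}) or exceeds the
    largest listed length (longer saturations are masked as a conservative
    superset). Returns a boolean mask shaped like the samples; the recording
    itself is not modified.
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    run_lengths = frozenset(int(r) for r in run_lengths)
    if not run_lengths:
        raise ValueError("run_lengths must be non-empty")
    longest = max(run_lengths)
    exceed = np.abs(recording.samples) > amp_threshold
    mask = np.zeros_like(exceed)
    for ch in range(recording.n_channels):
        for start, length in _runs(exceed[ch]):
            if length in run_lengths or length > longest:
                mask[ch, start : start + length] = True
    return mask


def detect_blinks(
    recording: EEGRecording,
    frontal_channels: tuple[str, ...] = BLINK_CHANNELS,
    k: float = 6.0,
    min_duration_s: float = 0.05,
) -> np.ndarray:
    """Mask stereotyped blink deflections on the frontal channels.

    A threshold detector: the frontal channels are band-passed to 0.5-4 Hz
    and a time point is blink-contaminated when the band-passed amplitude
    exceeds ``k`` times that channel's median absolute deviation for at least
    ``min_duration_s`` seconds. Blink intervals found on any frontal channel
    are masked across *all* channels (a blink contaminates the whole epoch).
    Returns a boolean mask shaped like the samples.
    """
    present = [ch for ch in frontal_channels if recording.has_channel(ch)]
    if not present:
        raise ValueError("no frontal channels present for blink detection")
    lo, hi = 0.5, 4.0
    idx = [recording.channel_index(ch) for ch in present]
    bp = _filter_array(recording.samples[idx], recording.fs, lo=lo, hi=hi)
    min_run = max(1, int(round(min_duration_s * recording.fs)))
    time_mask = np.zeros(recording.n_samples, dtype=bool)
    for row in bp:
        mad = np.median(np.abs(row - np.median(row)))
        if mad == 0:
            continue
        exceed = np.abs(row) > k * mad
        for start, length in _runs(exceed):
            if length >= min_run:
                time_mask[start : start + length] = True
    return np.broadcast_to(time_mask, recording.samples.shape).copy()


def remove_outliers(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass 3-SD outlier removal on a numeric series.

    Points with ``|x - mean| > 3*SD`` (mean and SD of the full input series,
    computed once — the rule is deliberately not iterated) are dropped;
    survivor order is preserved. Returns ``(cleaned, removed_indices)``.
    A constant series has SD 0 and is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D series")
    if values.size < 2:
        raise ValueError("series must have at least two points")
    sd = values.std()
    if sd == 0:
        return values.copy(), np.array([], dtype=int)
    out = np.abs(values - values.mean()) > 3 * sd
    return values[~out], np.flatnonzero(out)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _filter_array(
    samples: np.ndarray, fs: float, lo: float | None = None, hi: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filtering of a channels × time array."""
    nyq = fs / 2.0
    if hi is not None and hi >= nyq * 0.999:
        hi = None  # upper edge at/above Nyquist: high-pass only
    if lo is not None and lo <= 0:
        lo = None
    if lo is None and hi is None:
        return samples.copy()
    if lo is not None and hi is not None:
        sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    elif lo is not None:
        sos = sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, samples, axis=-1)


def apply_notch(recording: EEGRecording, freq: float = 60.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase notch filter (mains interference removal).

    Attenuates a sinusoid at ``freq`` by well over 20 dB while leaving
    components at half that frequency essentially untouched (< 1 dB).
    """
    if not 0 < freq < recording.fs / 2:
        raise ValueError(f"notch frequency must be in (0, fs/2), got {freq}")
    b, a = sps.iirnotch(freq, Q=q, fs=recording.fs)
    filtered = sps.filtfilt(b, a, recording.samples, axis=-1)
    return recording.with_samples(filtered)


def apply_bandpass(recording: EEGRecording, lo: float, hi: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass.

    Used both for the broadband 0.5-128 Hz cleaning pass and per analysis
    band ahead of phase extraction. An upper edge equal to Nyquist degrades
    to a pure high-pass; an upper edge above Nyquist is an error.
    """
    nyq = recording.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi > nyq:
        raise ValueError(f"upper edge {hi} Hz exceeds Nyquist ({nyq} Hz)")
    filtered = _filter_array(recording.samples, recording.fs, lo=lo, hi=hi, order=order)
    return recording.with_samples(filtered)


def bandpass_band(recording: EEGRecording, band: BandDefinition) -> EEGRecording:
    """Band-pass a recording to one of the canonical analysis bands."""
    return apply_bandpass(recording, band.lo, band.hi)


# ---------------------------------------------------------------------------
# spectral estimation
# ---------------------------------------------------------------------------

@dataclass
class PSDSpectrogram:
    """Windowed power spectral density per channel (channel × window × freq).

    Windows rejected by the artifact policy hold NaN; downstream averages
    use NaN-aware reductions. Values are densities (power per Hz), so band
    power is the integral of the density over the band.
    """

    values: np.ndarray
    freq_bins: np.ndarray
    window_sec: float
    overlap_frac: float
    channel_names: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be channel × window × frequency")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < -1e-12:
                raise ValueError("PSD values must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in spectrogram") from None

    def band_power(self, band: BandDefinition) -> np.ndarray:
        """Integrated power in ``band`` per channel and window (NaN where rejected)."""
        sel = (self.freq_bins >= band.lo) & (self.freq_bins < band.hi)
        if not sel.any():
            raise ValueError(f"no frequency bins inside band {band.name}")
        return np.trapezoid(self.values[:, :, sel], self.freq_bins[sel], axis=-1)

    def total_power(self) -> np.ndarray:
        """Integrated power over the full spectrum, per channel and window."""
        return np.trapezoid(self.values, self.freq_bins, axis=-1)


def _interpolate_masked(seg: np.ndarray, seg_mask: np.ndarray) -> np.ndarray:
    good = np.flatnonzero(~seg_mask)
    bad = np.flatnonzero(seg_mask)
    if bad.size == 0 or good.size == 0:
        return seg
    out = seg.copy()
    out[bad] = np.interp(bad, good, seg[good])
    return out


def compute_psd(
    recording: EEGRecording,
    window_sec: float = 1.0,
    overlap_frac: float = 0.5,
    kaiser_beta: float = KAISER_BETA,
    reject_fraction: float = WINDOW_REJECT_FRACTION,
) -> PSDSpectrogram:
    """Short-time PSD with a Kaiser moving window (default 1 s, 50% overlap).

    Per channel and window, a one-sided periodogram with a Kaiser taper.
    Windows whose artifact-mask fraction exceeds ``reject_fraction`` are
    dropped (NaN); lighter contamination is repaired by linear interpolation
    across the masked samples before the FFT.
    """
    win = int(round(window_sec * recording.fs))
    if win < 2:
        raise ValueError("window must cover at least two samples")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    if recording.n_samples < win:
        raise ValueError("recording shorter than one analysis window")
    hop = max(1, int(round(win * (1 - overlap_frac))))
    n_win = 1 + (recording.n_samples - win) // hop
    taper = ("kaiser", kaiser_beta)
    freq_bins = np.fft.rfftfreq(win, d=1.0 / recording.fs)
    values = np.full((recording.n_channels, n_win, freq_bins.size), np.nan)
    for w in range(n_win):
        start = w * hop
        seg = recording.samples[:, start : start + win]
        seg_mask = recording.artifact_mask[:, start : start + win]
        for ch in range(recording.n_channels):
            frac = seg_mask[ch].mean()
            if frac > reject_fraction:
                continue
            data = seg[ch]
            if frac > 0:
                data = _interpolate_masked(data, seg_mask[ch])
            _, psd = sps.periodogram(
                data, fs=recording.fs, window=taper, detrend=False
            )
            values[ch, w] = psd
    return PSDSpectrogram(
        values=values,
        freq_bins=freq_bins,
        window_sec=window_sec,
        overlap_frac=overlap_frac,
        channel_names=recording.channel_names,
        fs=recording.fs,
    )


# ---------------------------------------------------------------------------
# standard cleaning chain
# ---------------------------------------------------------------------------

def preprocess(
    recording: EEGRecording,
    notch_hz: float = 60.0,
    bandpass: tuple[float, float] = (0.5, 128.0),
    spike_threshold: float = SPIKE_AMPLITUDE,
    blink_k: float = 6.0,
) -> EEGRecording:
    """Full cleaning chain: spike masking → notch → band-pass → blink masking.

    Artifact detection runs on the raw amplitudes (spikes) and on the
    filtered signal (blinks); masks accumulate on the returned recording.
    """
    spikes = detect_spike_artifacts(recording, amp_threshold=spike_threshold)
    rec = recording.with_mask(spikes)
    rec = apply_notch(rec, notch_hz)
    rec = apply_bandpass(rec, *bandpass)
    blinks = detect_blinks(rec, k=blink_k)
    return rec.with_mask(blinks)
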