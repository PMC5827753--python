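"""Synthetic data calibrated to the study conditions.

Two generators make every pipeline stage testable without the (non-deposited)
intraoperative recordings:

* a **feature-level** generator drawing 96-dimensional two-group datasets
  whose key-feature means and standard errors match the published group
  tables (simple task: 63 trustworthy / 24 concerning with three γ-band key
  features; complex task: 43/40 with seven γ-band functional features plus
  blink rate and asymmetry index). Group SDs derive from the printed
  standard errors via SD = SE·√N. Non-key features get identical means in
  both groups, so they carry no label information. Features are drawn
  independently unless a correlation matrix is supplied — no inter-feature
  covariance is published, so synthetic classification accuracies are
  upper-bound analogues of the real ones.

* a **signal-level** generator producing multichannel oscillatory EEG with
  controllable per-band phase coupling: each channel's band phase is a
  convex mixture (weight g) of a shared band oscillator and an independent
  phase random walk, so the estimated phase-locking value is ≈1 at g = 1,
  at the 1/√P noise floor at g = 0, and increases monotonically in g.
  Blink templates and supra-threshold spike runs can be injected at known
  times to exercise the artifact detectors.

All outputs are fully determined by (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_names import (
    ALL_FEATURE_NAMES,
    FUNCTIONAL_NAMES,
    KEY_FEATURES_LND,
    KEY_FEATURES_UVA,
    UNIT_INTERVAL_FEATURES,
)
from .labels import CONCERNING, TRUSTWORTHY
from .parcellation import CHANNELS_20
from .recording import EEGRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature-level generator
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Two-group per-feature means and SEs plus group sizes.

    ``table`` is indexed by the 96 canonical feature names with columns
    mean_trustworthy / se_trustworthy / mean_concerning / se_concerning.
    Group SDs are SE·√N for the respective group size.
    """

    task: str
    n_trustworthy: int
    n_concerning: int
    table: pd.DataFrame
    key_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_trustworthy < 2 or self.n_concerning < 2:
            raise ValueError("group sizes must exceed 1")
        unknown = [f for f in self.table.index if f not in ALL_FEATURE_NAMES]
        if unknown:
            raise ValueError(f"non-canonical feature names: {unknown}")
        if (self.table[["se_trustworthy", "se_concerning"]] <= 0).any().any():
            raise ValueError("standard errors must be positive")

    def sd(self, feature: str, group: str) -> float:
        n = self.n_trustworthy if group == TRUSTWORTHY else self.n_concerning
        se = self.table.loc[feature, f"se_{group}"]
        return float(se * np.sqrt(n))


#: Background (non-key) feature means/SDs: identical in both groups.
#: Units: ML in integrated-power units, SA likewise, CT seconds (recordings
#: ran 30 ± 12 min), probabilities and phase-locking averages dimensionless.
_BACKGROUND: dict[str, tuple[float, float]] = {
    "MW": (0.5, 0.15),
    "E": (0.5, 0.15),
    "SA": (10.0, 2.0),
    "BR": (0.77, 0.10),
    "AI": (-0.17, 0.15),
    "CT": (1800.0, 720.0),
}
for _sys in ("F", "PF", "C", "T", "Pa", "O"):
    _BACKGROUND[f"ML_{_sys}"] = (50.0, 10.0)
for _name in FUNCTIONAL_NAMES:
    _BACKGROUND[_name] = (0.5, 0.08)

#: Printed key-feature group values: name -> (mean_t, se_t, mean_c, se_c).
#: The one SE printed as 0.00 is floored at 0.005, the rounding bound of the
#: two-decimal display.
_UVA_KEY = {
    "γ:F": (0.37, 0.01, 0.75, 0.03),
    "γ:F-Pa": (0.35, 0.01, 0.58, 0.03),
    "γ:F-C": (0.35, 0.01, 0.68, 0.03),
}
_LND_KEY = {
    "γ:F": (0.34, 0.01, 0.73, 0.02),
    "γ:F-PF": (0.42, 0.01, 0.73, 0.02),
    "γ:PF-Pa": (0.55, 0.01, 0.79, 0.02),
    "γ:F-Pa": (0.38, 0.01, 0.68, 0.02),
    "γ:T-O": (0.49, 0.01, 0.74, 0.02),
    "γ:F-C": (0.38, 0.02, 0.73, 0.02),
    "γ:F-O": (0.48, 0.005, 0.73, 0.02),
    "BR": (0.83, 0.02, 0.71, 0.02),
    "AI": (-0.23, 0.03, -0.10, 0.02),
}

#: Legal ranges used to clip Gaussian draws.
_BOUNDS: dict[str, tuple[float, float]] = {"AI": (-1.0, 1.0), "CT": (1.0, np.inf), "SA": (0.0, np.inf)}
for _sys in ("F", "PF", "C", "T", "Pa", "O"):
    _BOUNDS[f"ML_{_sys}"] = (0.0, np.inf)
for _name in UNIT_INTERVAL_FEATURES:
    _BOUNDS[_name] = (0.0, 1.0)


def _build_spec(task, n_t, n_c, key_values, key_order) -> GroupSpec:
    rows = {}
    for name in ALL_FEATURE_NAMES:
        if name in key_values:
            m_t, se_t, m_c, se_c = key_values[name]
        else:
            mean, sd = _BACKGROUND[name]
            m_t = m_c = mean
            se_t = sd / np.sqrt(n_t)
            se_c = sd / np.sqrt(n_c)
        rows[name] = dict(
            mean_trustworthy=m_t, se_trustworthy=se_t,
            mean_concerning=m_c, se_concerning=se_c,
        )
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(ALL_FEATURE_NAMES)]
    return GroupSpec(
        task=task, n_trustworthy=n_t, n_concerning=n_c,
        table=table, key_features=tuple(key_order),
    )


def uva_group_spec() -> GroupSpec:
    """Two-group spec for the simple task: N = 63/24, three γ-band key features."""
    return _build_spec("UVA", 63, 24, _UVA_KEY, KEY_FEATURES_UVA)


def lnd_group_spec() -> GroupSpec:
    """Two-group spec for the complex task: N = 43/40, nine key features."""
    return _build_spec("LND", 43, 40, _LND_KEY, KEY_FEATURES_LND)


def generate_feature_dataset(
    spec: GroupSpec,
    seed: int = 0,
    correlation: pd.DataFrame | None = None,
    n_trustworthy: int | None = None,
    n_concerning: int | None = None,
) -> pd.DataFrame:
    """Draw a labelled 96-column feature table from a group spec.

    Independent Gaussian draws per feature and group at the spec's mean and
    SD (= SE·√N), clipped to each feature's legal range. An optional
    ``correlation`` matrix (features × features, e.g. carrying published
    pairwise r values) imposes a joint Gaussian correlation structure via
    its Cholesky factor. Row order is shuffled deterministically by seed.
    """
    rng = np.random.default_rng(seed)
    names = list(spec.table.index)
    chol = None
    if correlation is not None:
        corr = correlation.reindex(index=names, columns=names).fillna(0.0).to_numpy()
        np.fill_diagonal(corr, 1.0)
        corr = (corr + corr.T) / 2
        # nudge to the nearest PSD matrix if the user-specified entries are not
        w, V = np.linalg.eigh(corr)
        if w.min() < 1e-10:
            corr = V @ np.diag(np.clip(w, 1e-10, None)) @ V.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        chol = np.linalg.cholesky(corr)

    frames = []
    sizes = {
        TRUSTWORTHY: spec.n_trustworthy if n_trustworthy is None else n_trustworthy,
        CONCERNING: spec.n_concerning if n_concerning is None else n_concerning,
    }
    for group, n in sizes.items():
        means = spec.table[f"mean_{group}"].to_numpy()
        sds = np.array([spec.sd(f, group) for f in names])
        z = rng.standard_normal((n, len(names)))
        if chol is not None:
            z = z @ chol.T
        draws = means + sds * z
        for j, name in enumerate(names):
            lo, hi = _BOUNDS.get(name, (-np.inf, np.inf))
            draws[:, j] = np.clip(draws[:, j], lo, hi)
        frame = pd.DataFrame(draws, columns=names)
        frame["label"] = group
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["task"] = spec.task
    perm = rng.permutation(len(out))
    return out.iloc[perm].reset_index(drop=True)


def combined_trust_complexity_dataset(seed: int = 0) -> pd.DataFrame:
    """Pooled two-task table where features track trust but not task.

    All 170 recordings (106 trustworthy, 64 concerning — the pooled group
    sizes of both tasks) are drawn from the complex-task group spec, so the
    nine key features differ by trust group; task labels (87 simple / 83
    complex) are then assigned by a random permutation independent of the
    features. Classifying task from these features can only reach chance.
    """
    spec = lnd_group_spec()
    df = generate_feature_dataset(spec, seed=seed, n_trustworthy=106, n_concerning=64)
    rng = np.random.default_rng(seed + 1)
    task = np.array(["UVA"] * 87 + ["LND"] * 83, dtype=object)
    df["task"] = task[rng.permutation(len(task))]
    return df


# ---------------------------------------------------------------------------
# signal-level generator
# ---------------------------------------------------------------------------

@dataclass
class CouplingSpec:
    """Ground-truth phase-coupling specification for synthetic EEG.

    ``coupling`` maps a band symbol to either a scalar g applied to every
    channel or a per-channel array; g is the convex weight of the shared
    band oscillator in each channel's phase. ``center_freqs`` places each
    band's oscillator (must lie inside the band). ``phase_jitter`` is the
    per-sample SD (radians) of the independent phase random walks — large
    enough that uncoupled phases decorrelate well inside a recording.
    """

    coupling: dict[str, object] = field(default_factory=lambda: {"γ": 0.0})
    center_freqs: dict[str, float] = field(
        default_factory=lambda: {"θ": 6.0, "α": 10.0, "β": 20.0, "γ": 45.0}
    )
    amplitudes: dict[str, float] = field(default_factory=dict)
    phase_jitter: float = 0.3
    noise_sd: float = 0.1

    def g_array(self, band_symbol: str, n_channels: int) -> np.ndarray:
        g = np.broadcast_to(
            np.asarray(self.coupling[band_symbol], dtype=float), (n_channels,)
        ).copy()
        if g.min() < 0 or g.max() > 1:
            raise ValueError("coupling strengths must lie in [0, 1]")
        return g


_BAND_RANGES = {"θ": (4.0, 8.0), "α": (8.0, 12.0), "β": (12.0, 35.0), "γ": (35.0, 60.0)}


def generate_coupled_eeg(
    spec: CouplingSpec,
    duration_s: float = 60.0,
    fs: float = 256.0,
    channels: tuple[str, ...] = CHANNELS_20,
    seed: int = 0,
) -> tuple[EEGRecording, dict[str, np.ndarray]]:
    """Multichannel oscillatory EEG with known per-band phase coupling.

    Returns ``(recording, ground_truth)`` where ground_truth maps each band
    symbol to the per-channel coupling array g. A pair with g_i = g_j = 1
    shares its band phase exactly; g = 0 channels run independent
    random-walk phases.
    """
    n = int(round(duration_s * fs))
    if n < 2 * fs:
        raise ValueError("need at least two seconds of samples")
    n_ch = len(channels)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    samples = np.zeros((n_ch, n))
    truth: dict[str, np.ndarray] = {}
    for band_symbol, _g in spec.coupling.items():
        lo, hi = _BAND_RANGES[band_symbol]
        f0 = spec.center_freqs.get(band_symbol, (lo + hi) / 2)
        if not lo <= f0 < hi:
            raise ValueError(f"center frequency {f0} Hz outside band {band_symbol}")
        g = spec.g_array(band_symbol, n_ch)
        truth[band_symbol] = g
        amp = spec.amplitudes.get(band_symbol, 1.0)
        shared_walk = np.cumsum(rng.normal(0, spec.phase_jitter, size=n))
        base = 2 * np.pi * f0 * t
        for ch in range(n_ch):
            own_walk = np.cumsum(rng.normal(0, spec.phase_jitter, size=n))
            phase = base + g[ch] * shared_walk + (1 - g[ch]) * own_walk
            phase += rng.uniform(0, 2 * np.pi)  # random initial phase offset
            samples[ch] += amp * np.cos(phase)
    samples += rng.normal(0, spec.noise_sd, size=samples.shape)
    rec = EEGRecording(samples=samples, fs=fs, channel_names=channels)
    return rec, truth


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

_BLINK_DURATION_S = 0.4


def _place_intervals(rng, n_events, length, n_samples, occupied, max_tries=10000):
    """Rejection-sample non-overlapping intervals; log when crowded."""
    placed = []
    tries = 0
    while len(placed) < n_events and tries < max_tries:
        tries += 1
        start = int(rng.integers(0, n_samples - length))
        sl = slice(max(0, start - 2), min(n_samples, start + length + 2))
        if occupied[sl].any():
            continue
        occupied[start : start + length] = True
        placed.append((start, length))
    if len(placed) < n_events:
        logger.warning("placed only %d of %d events (crowded recording)", len(placed), n_events)
    return placed


def inject_artifacts(
    recording: EEGRecording,
    blink_rate_target: float = 0.0,
    spike_count: int = 0,
    seed: int = 0,
    blink_amplitude: float = 60.0,
    spike_amplitude: float = 50.0,
    run_lengths: tuple[int, ...] = (3, 5, 7),
) -> tuple[EEGRecording, dict[str, list]]:
    """Add blink templates and spike runs at known times.

    Blinks are 0.4 s raised-cosine frontal transients (0.5-4 Hz content)
    placed so that the blink-contaminated fraction of time points matches
    ``blink_rate_target``; spikes are supra-threshold runs with lengths
    cycling through ``run_lengths`` on random channels. Returns the
    augmented recording and ground truth:
    ``{"blinks": [(start, stop)], "spikes": [(channel, start, length)]}``.
    Zero targets return the recording unchanged.
    """
    if not 0 <= blink_rate_target < 1:
        raise ValueError("blink_rate_target must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = recording.samples.copy()
    n = recording.n_samples
    truth: dict[str, list] = {"blinks": [], "spikes": []}
    occupied = np.zeros(n, dtype=bool)

    blink_len = int(round(_BLINK_DURATION_S * recording.fs))
    n_blinks = int(round(blink_rate_target * n / blink_len))
    if n_blinks:
        frontal = [c for c in ("Fp1", "Fp2", "F3", "F4") if recording.has_channel(c)]
        if not frontal:
            raise ValueError("no frontal channels available for blink injection")
        template = blink_amplitude * 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_len) / blink_len))
        for start, length in _place_intervals(rng, n_blinks, blink_len, n, occupied):
            for ch in frontal:
                samples[recording.channel_index(ch), start : start + length] += template
            truth["blinks"].append((start, start + length))

    if spike_count:
        lengths = [run_lengths[i % len(run_lengths)] for i in range(spike_count)]
        for length in lengths:
            placed = _place_intervals(rng, 1, length, n, occupied)
            if not placed:
                break
            start, _ = placed[0]
            ch = int(rng.integers(0, recording.n_channels))
            sign = 1 if rng.random() < 0.5 else -1
            samples[ch, start : start + length] = sign * spike_amplitude
            truth["spikes"].append((ch, start, length))

    out = recording.with_samples(samples)
    return out, truth
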