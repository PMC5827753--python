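"""Phase-synchronization functional connectivity.

Each analysis band is isolated with a zero-phase band-pass, the analytic
signal gives every channel an instantaneous phase, and each channel pair is
scored with the phase-locking value

    Γ_xy = √[(Σ_t cos Δφ(t))² + (Σ_t sin Δφ(t))²] / P,

the resultant length of the pairwise phase difference over the P retained
(artifact-free on both channels) time points. Γ is 1 iff the difference is
constant and decays to the 1/√P noise floor for unrelated signals. The
signed wrapped difference enters the sums — the cosine term is insensitive
to the sign convention and using the signed value keeps Γ invariant under a
common phase shift and unbiased under the null, which an absolute-valued
difference would not. The absolute wrapped difference (range [0, π]) is
still what :func:`phase_difference` reports for diagnostics.

Per band, the 21 system-level aggregates (6 within-system strengths,
15 between-system communications) are block means of the Γ matrix over the
six-system parcellation; four bands give the 84-dimensional functional
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .bands import BANDS, BandDefinition, get_band
from .feature_names import communication_name, strength_name
from .parcellation import DEFAULT_PARCELLATION, SYSTEMS, SystemParcellation
from .preprocessing import bandpass_band
from .recording import EEGRecording


@dataclass
class PhaseSeries:
    """Per-channel instantaneous phase (radians, wrapped to [-π, π])."""

    phi: np.ndarray  # channels × time
    band: BandDefinition
    channel_names: tuple[str, ...]
    fs: float
    valid: np.ndarray  # channels × time bool, False where artifact-masked

    def __post_init__(self) -> None:
        if np.abs(self.phi).max(initial=0.0) > np.pi + 1e-9:
            raise ValueError("phases must be wrapped to [-π, π]")
        if self.valid.shape != self.phi.shape:
            raise ValueError("valid mask must match phi shape")


@dataclass
class ConnectivityMatrix:
    """Symmetric channels × channels matrix of Γ for one band.

    ``pair_counts[i, j]`` is P, the number of retained time points the pair
    was averaged over. The diagonal is 1 by definition.
    """

    values: np.ndarray
    band: BandDefinition
    channel_names: tuple[str, ...]
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("Γ entries must lie in [0, 1]")

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_names, columns=self.channel_names)


def instantaneous_phase(recording: EEGRecording, band) -> PhaseSeries:
    """Band-limit the recording and extract analytic-signal phase per channel."""
    band = get_band(band)
    if band.hi > recording.fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz exceeds Nyquist ({recording.fs / 2} Hz)"
        )
    filtered = bandpass_band(recording, band)
    phi = np.angle(hilbert(filtered.samples, axis=-1))
    return PhaseSeries(
        phi=phi,
        band=band,
        channel_names=recording.channel_names,
        fs=recording.fs,
        valid=~recording.artifact_mask,
    )


def phase_difference(phi_x: np.ndarray, phi_y: np.ndarray) -> np.ndarray:
    """Absolute pairwise phase difference, wrapped to [0, π] for reporting."""
    phi_x = np.asarray(phi_x, dtype=float)
    phi_y = np.asarray(phi_y, dtype=float)
    if phi_x.shape != phi_y.shape:
        raise ValueError("phase series must have equal length")
    d = np.abs(phi_x - phi_y) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def phase_sync_index(dphi: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Γ of a phase-difference series: resultant length over retained points.

    ``valid`` (optional boolean mask) excludes artifact-contaminated points
    before the summation; an empty retained set is an unusable pair.
    """
    dphi = np.asarray(dphi, dtype=float)
    if valid is not None:
        dphi = dphi[np.asarray(valid, dtype=bool)]
    P = dphi.size
    if P == 0:
        raise ValueError("no retained time points (P = 0)")
    return float(np.hypot(np.cos(dphi).sum(), np.sin(dphi).sum()) / P)


def connectivity_matrix(
    recording: EEGRecording,
    band,
    parcellation: SystemParcellation | None = None,
) -> ConnectivityMatrix:
    """Γ for every unordered channel pair in one band.

    Masked samples are dropped pairwise: a time point is excluded for a pair
    when either channel is masked there, and P is the per-pair retained
    count. Vectorized over pairs via the unit-phasor Gram matrix.
    """
    if recording.n_channels < 2:
        raise ValueError("need at least two channels")
    phases = instantaneous_phase(recording, band)
    valid = phases.valid
    Z = np.exp(1j * phases.phi) * valid
    counts = valid.astype(float) @ valid.T.astype(float)
    off = ~np.eye(recording.n_channels, dtype=bool)
    if np.any(counts[off] == 0):
        raise ValueError("a channel pair has no jointly retained samples (P = 0)")
    resultant = np.abs(Z @ Z.conj().T)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = resultant / counts
    gamma = np.clip(gamma, 0.0, 1.0)
    np.fill_diagonal(gamma, 1.0)
    gamma = (gamma + gamma.T) / 2
    return ConnectivityMatrix(
        values=gamma,
        band=phases.band,
        channel_names=recording.channel_names,
        pair_counts=counts,
    )


def _system_indices(matrix: ConnectivityMatrix, parcellation: SystemParcellation, k: str):
    return [
        matrix.channel_index(ch)
        for ch in parcellation.channels(k)
        if ch in matrix.channel_names
    ]


def system_strength(
    matrix: ConnectivityMatrix,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
    k: str = "F",
) -> float:
    """Mean Γ over distinct within-system channel pairs (self-pairs excluded).

    Including the unit diagonal would floor two-channel systems at 0.5, so
    only the |S_k|·(|S_k|−1)/2 off-diagonal pairs are averaged.
    """
    idx = _system_indices(matrix, parcellation, k)
    if len(idx) < 2:
        raise ValueError(f"system {k!r} has fewer than two channels in the matrix")
    vals = [matrix.values[i, j] for i, j in combinations(idx, 2)]
    return float(np.mean(vals))


def system_communication(
    matrix: ConnectivityMatrix,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
    k1: str = "F",
    k2: str = "Pa",
) -> float:
    """C_{k1,k2} = Σ_{i∈k1, j∈k2} Γ_ij / (|S_k1|·|S_k2|)."""
    if k1 == k2:
        raise ValueError("communication requires two distinct systems (use system_strength)")
    idx1 = _system_indices(matrix, parcellation, k1)
    idx2 = _system_indices(matrix, parcellation, k2)
    if not idx1 or not idx2:
        raise ValueError("a system has no channels present in the matrix")
    block = matrix.values[np.ix_(idx1, idx2)]
    return float(block.mean())


def functional_feature_vector(
    recording: EEGRecording,
    parcellation: SystemParcellation = DEFAULT_PARCELLATION,
    bands: tuple[BandDefinition, ...] = BANDS,
) -> pd.Series:
    """All strength/communication features for all bands (84 values, [0, 1])."""
    out: dict[str, float] = {}
    for band in bands:
        matrix = connectivity_matrix(recording, band, parcellation)
        for sys in SYSTEMS:
            out[strength_name(band, sys)] = system_strength(matrix, parcellation, sys)
        for a, b in combinations(SYSTEMS, 2):
            out[communication_name(band, a, b)] = system_communication(
                matrix, parcellation, a, b
            )
    return pd.Series(out)
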