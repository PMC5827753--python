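"""Phase extraction, the phase-locking value Γ and system-level aggregates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurotrust.bands import ALPHA, BETA, GAMMA
from neurotrust.connectivity import (
    connectivity_matrix,
    functional_feature_vector,
    instantaneous_phase,
    phase_difference,
    phase_sync_index,
    system_communication,
    system_strength,
)
from neurotrust.parcellation import CHANNELS_20, DEFAULT_PARCELLATION
from neurotrust.synthetic import CouplingSpec, generate_coupled_eeg

from conftest import FS, make_recording, sine


def plv_oracle(dphi):
    """Independent two-line summation oracle for Γ."""
    return np.sqrt(np.cos(dphi).sum() ** 2 + np.sin(dphi).sum() ** 2) / len(dphi)


class TestInstantaneousPhase:
    def test_linear_phase_advance(self):
        rec = make_recording(sine(10.0, duration_s=8))
        phases = instantaneous_phase(rec, ALPHA)
        mid = slice(512, -512)
        slope = np.diff(np.unwrap(phases.phi[0][mid])).mean() * FS
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_identical_channels_identical_phase(self):
        x = sine(10.0, duration_s=4)
        rec = make_recording(np.vstack([x, x]), names=("C3", "C4"))
        phases = instantaneous_phase(rec, ALPHA)
        np.testing.assert_allclose(phases.phi[0], phases.phi[1])

    def test_quarter_period_delay_is_half_pi(self):
        f = 10.0
        x = sine(f, duration_s=8)
        y = sine(f, duration_s=8, phase=-np.pi / 2)  # quarter-period delay
        rec = make_recording(np.vstack([x, y]), names=("C3", "C4"))
        phases = instantaneous_phase(rec, ALPHA)
        mid = slice(512, -512)
        d = phase_difference(phases.phi[0][mid], phases.phi[1][mid])
        assert np.median(d) == pytest.approx(np.pi / 2, rel=0.02)

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(sine(10.0), fs=64.0)
        with pytest.raises(ValueError):
            instantaneous_phase(rec, GAMMA)  # gamma tops out above 32 Hz

    def test_phases_wrapped(self):
        rec = make_recording(sine(45.0, duration_s=4))
        phases = instantaneous_phase(rec, GAMMA)
        assert np.abs(phases.phi).max() <= np.pi + 1e-12


class TestPhaseDifference:
    def test_identical_series_zero(self):
        x = np.linspace(-np.pi, np.pi, 50)
        np.testing.assert_allclose(phase_difference(x, x), 0.0)

    def test_constant_offset(self):
        x = np.zeros(10)
        np.testing.assert_allclose(phase_difference(x + 0.7, x), 0.7)

    def test_direct_example(self):
        np.testing.assert_allclose(
            phase_difference(np.array([0.0, np.pi / 2]), np.zeros(2)),
            [0.0, np.pi / 2],
        )

    def test_wrapped_to_half_circle(self):
        d = phase_difference(np.array([np.pi * 0.9]), np.array([-np.pi * 0.9]))
        assert d[0] == pytest.approx(0.2 * np.pi)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            phase_difference(np.zeros(3), np.zeros(4))


class TestPhaseSyncIndex:
    def test_constant_difference_is_unity(self):
        assert phase_sync_index(np.full(100, 0.7)) == pytest.approx(1.0)

    def test_antipodal_cancellation(self):
        assert phase_sync_index(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_derived_example(self):
        gamma = phase_sync_index(np.array([0.0, np.pi / 2, np.pi / 4]))
        assert gamma == pytest.approx(0.8047, abs=1e-4)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            dphi = rng.uniform(-np.pi, np.pi, size=rng.integers(2, 40))
            assert phase_sync_index(dphi) == pytest.approx(plv_oracle(dphi), abs=1e-12)

    def test_mask_exclusion(self):
        dphi = np.array([0.0, 0.0, np.pi, np.pi])
        valid = np.array([True, True, False, False])
        assert phase_sync_index(dphi, valid) == pytest.approx(1.0)

    def test_empty_after_masking_rejected(self):
        with pytest.raises(ValueError):
            phase_sync_index(np.array([1.0]), np.array([False]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=30),
        st.floats(-10, 10),
    )
    def test_invariant_under_common_offset(self, dphi, c):
        dphi = np.asarray(dphi)
        a = phase_sync_index(dphi)
        b = phase_sync_index(dphi + c)
        assert 0.0 <= a <= 1.0 + 1e-12
        assert a == pytest.approx(b, abs=1e-9)


class TestConnectivityMatrix:
    def test_identical_channels_all_ones(self):
        x = sine(10.0, duration_s=4) + 0.01 * np.random.default_rng(0).normal(size=1024)
        rec = make_recording(np.vstack([x, x, x]), names=("C3", "Cz", "C4"))
        m = connectivity_matrix(rec, ALPHA)
        np.testing.assert_allclose(m.values, 1.0, atol=1e-9)

    def test_independent_noise_near_floor(self, rng):
        # band-limited independent noise decorrelates: Γ ~ 1/sqrt(P_eff)
        rec = make_recording(rng.normal(0, 1, (4, 10000)), names=("C3", "Cz", "C4", "P3"))
        m = connectivity_matrix(rec, BETA)
        off = m.values[~np.eye(4, dtype=bool)]
        assert off.max() < 0.1

    def test_coupled_pair_detected(self):
        spec = CouplingSpec(coupling={"γ": np.array([1.0, 1.0, 0.0])})
        rec, _ = generate_coupled_eeg(spec, duration_s=30, channels=("C3", "C4", "P3"), seed=5)
        m = connectivity_matrix(rec, GAMMA)
        assert m.values[0, 1] > 0.95
        assert m.values[0, 2] < 0.3

    def test_symmetry_diagonal_and_range(self, rng):
        rec = make_recording(rng.normal(0, 1, (5, 4000)), names=CHANNELS_20[:5])
        m = connectivity_matrix(rec, ALPHA)
        np.testing.assert_allclose(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert (m.values >= 0).all() and (m.values <= 1).all()

    def test_pairwise_mask_exclusion_counts(self, rng):
        rec = make_recording(rng.normal(0, 1, (2, 1000)), names=("C3", "C4"))
        rec.artifact_mask[0, :100] = True
        rec.artifact_mask[1, 900:] = True
        m = connectivity_matrix(rec, ALPHA)
        assert m.pair_counts[0, 1] == 800

    def test_single_channel_rejected(self, rng):
        rec = make_recording(rng.normal(0, 1, (1, 1000)), names=("C3",))
        with pytest.raises(ValueError):
            connectivity_matrix(rec, ALPHA)


def block_matrix(values_dict, names):
    """Build a ConnectivityMatrix with prescribed entries (symmetrized)."""
    from neurotrust.connectivity import ConnectivityMatrix

    n = len(names)
    vals = np.full((n, n), 0.0)
    np.fill_diagonal(vals, 1.0)
    for (a, b), v in values_dict.items():
        i, j = names.index(a), names.index(b)
        vals[i, j] = vals[j, i] = v
    return ConnectivityMatrix(
        values=vals, band=GAMMA, channel_names=tuple(names),
        pair_counts=np.full((n, n), 100.0),
    )


class TestSystemAggregates:
    def test_uniform_block_strength(self):
        names = ["Fp1", "Fp2"]
        m = block_matrix({("Fp1", "Fp2"): 0.5}, names)
        assert system_strength(m, k="PF") == pytest.approx(0.5)

    def test_strength_is_mean_of_distinct_pairs(self):
        names = ["F3", "Fz", "F4", "F7", "F8"]
        pair_vals = {}
        v = 0.05
        from itertools import combinations

        for a, b in combinations(names, 2):
            pair_vals[(a, b)] = v
            v += 0.05
        m = block_matrix(pair_vals, names)
        expected = np.mean(list(pair_vals.values()))
        assert system_strength(m, k="F") == pytest.approx(expected)

    def test_singleton_system_rejected(self):
        names = ["Fp1", "Fp2"]
        m = block_matrix({("Fp1", "Fp2"): 0.5}, names)
        with pytest.raises(ValueError):
            system_strength(m, k="F")  # no F channels in the matrix

    def test_communication_four_term_mean(self):
        names = ["Fp1", "Fp2", "O1", "O2"]
        m = block_matrix(
            {("Fp1", "O1"): 0.2, ("Fp1", "O2"): 0.4, ("Fp2", "O1"): 0.6, ("Fp2", "O2"): 0.8},
            names,
        )
        assert system_communication(m, k1="PF", k2="O") == pytest.approx(0.5)

    def test_all_unit_cross_entries(self):
        names = ["Fp1", "Fp2", "O1", "O2"]
        m = block_matrix(
            {(a, b): 1.0 for a in ("Fp1", "Fp2") for b in ("O1", "O2")}, names
        )
        assert system_communication(m, k1="PF", k2="O") == pytest.approx(1.0)

    def test_same_system_rejected(self):
        names = ["Fp1", "Fp2"]
        m = block_matrix({("Fp1", "Fp2"): 0.5}, names)
        with pytest.raises(ValueError):
            system_communication(m, k1="PF", k2="PF")

    def test_aggregates_bounded_by_block_extremes(self, rng):
        rec = make_recording(rng.normal(0, 1, (len(CHANNELS_20), 3000)), names=CHANNELS_20)
        m = connectivity_matrix(rec, ALPHA)
        for k in DEFAULT_PARCELLATION.system_names:
            s = system_strength(m, k=k)
            off = m.values[~np.eye(len(CHANNELS_20), dtype=bool)]
            assert off.min() - 1e-12 <= s <= off.max() + 1e-12


class TestFunctionalFeatureVector:
    def test_dimensional_contract(self, rng):
        rec = make_recording(rng.normal(0, 1, (len(CHANNELS_20), 4000)), names=CHANNELS_20)
        feats = functional_feature_vector(rec)
        assert len(feats) == 84
        assert np.isfinite(feats).all()
        assert ((feats >= 0) & (feats <= 1)).all()

    def test_identical_channels_all_ones(self):
        x = sine(10.0, duration_s=8) + sine(6.0, duration_s=8) + sine(20.0, duration_s=8) \
            + sine(45.0, duration_s=8) + 1e-6 * np.random.default_rng(1).normal(size=2048)
        rec = make_recording(np.tile(x, (len(CHANNELS_20), 1)), names=CHANNELS_20)
        feats = functional_feature_vector(rec)
        assert feats.min() > 0.999

    def test_band_specific_coupling(self):
        spec = CouplingSpec(coupling={"γ": 1.0, "θ": 0.0, "α": 0.0, "β": 0.0})
        rec, _ = generate_coupled_eeg(spec, duration_s=30, seed=9)
        feats = functional_feature_vector(rec)
        gamma_feats = feats[[n for n in feats.index if n.startswith("γ")]]
        theta_feats = feats[[n for n in feats.index if n.startswith("θ")]]
        assert gamma_feats.min() > 0.9
        assert theta_feats.max() < 0.4
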