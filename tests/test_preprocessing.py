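"""Artifact detection, filtering, spectral estimation and outlier removal."""

import numpy as np
import pytest

from neurotrust.preprocessing import (
    apply_bandpass,
    apply_notch,
    compute_psd,
    detect_blinks,
    detect_spike_artifacts,
    remove_outliers,
)
from neurotrust.synthetic import CouplingSpec, generate_coupled_eeg, inject_artifacts

from conftest import FS, make_recording, rms, sine


class TestSpikeDetection:
    def test_flat_signal_has_no_mask(self):
        rec = make_recording(np.zeros((2, 1000)))
        assert not detect_spike_artifacts(rec).any()

    @pytest.mark.parametrize(
        "run_length,expect_masked",
        [(3, True), (5, True), (7, True), (10, True), (4, False), (2, False)],
    )
    def test_run_length_policy(self, run_length, expect_masked):
        # lengths 3/5/7 are spikes; longer runs are saturations and masked as
        # a conservative superset; other short lengths are left alone
        x = np.zeros(1000)
        x[100 : 100 + run_length] = 50.0
        mask = detect_spike_artifacts(make_recording(x))
        expected = np.zeros(1000, dtype=bool)
        if expect_masked:
            expected[100 : 100 + run_length] = True
        np.testing.assert_array_equal(mask[0], expected)

    def test_exactly_the_excursion_is_masked(self):
        x = np.random.default_rng(0).normal(0, 1, 2000)
        x[500:505] = -50.0
        mask = detect_spike_artifacts(make_recording(x))
        # oracle: exhaustive run scan
        exceed = np.abs(x) > 40
        assert mask[0, 500:505].all()
        assert mask[0].sum() == 5
        assert not mask[0, ~exceed].any()

    def test_samples_unmodified(self):
        x = np.zeros(500)
        x[10:15] = 99.0
        rec = make_recording(x)
        before = rec.samples.copy()
        detect_spike_artifacts(rec)
        np.testing.assert_array_equal(rec.samples, before)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError):
            make_recording(np.empty((1, 0)))


class TestFilters:
    def test_notch_attenuates_target(self):
        rec = make_recording(sine(60.0))
        out = apply_notch(rec, 60.0)
        assert rms(out.samples[0]) < 0.1 * rms(rec.samples[0])

    def test_notch_preserves_half_frequency(self):
        rec = make_recording(sine(10.0))
        out = apply_notch(rec, 60.0)
        assert abs(rms(out.samples[0]) - rms(rec.samples[0])) < 0.01 * rms(rec.samples[0])

    def test_notch_removes_only_the_interference(self):
        clean = sine(10.0, duration_s=8)
        rec = make_recording(clean + sine(60.0, duration_s=8))
        out = apply_notch(rec, 60.0)
        mid = slice(512, -512)  # exclude filtfilt edge transients
        err = rms(out.samples[0][mid] - clean[mid])
        assert err < 0.05 * rms(clean[mid])

    def test_notch_frequency_validation(self):
        rec = make_recording(sine(10.0))
        with pytest.raises(ValueError):
            apply_notch(rec, FS / 2)

    def test_bandpass_passband_preserved(self):
        rec = make_recording(sine(6.0, duration_s=8))
        out = apply_bandpass(rec, 4.0, 8.0)
        mid = slice(256, -256)  # avoid edge transients
        assert abs(rms(out.samples[0][mid]) - rms(rec.samples[0][mid])) < 0.05 * rms(
            rec.samples[0][mid]
        )

    def test_bandpass_stopband_attenuated(self):
        rec = make_recording(sine(20.0, duration_s=8))
        out = apply_bandpass(rec, 4.0, 8.0)
        assert rms(out.samples[0]) < 0.1 * rms(rec.samples[0])

    def test_bandpass_rejects_band_above_nyquist(self):
        rec = make_recording(sine(10.0))
        with pytest.raises(ValueError):
            apply_bandpass(rec, 0.5, 200.0)

    def test_chirp_energy_confined_to_band(self):
        from scipy.signal import chirp

        from neurotrust.bands import BandDefinition

        t = np.arange(int(20 * FS)) / FS
        rec = make_recording(chirp(t, f0=1, f1=100, t1=20))
        out = apply_bandpass(rec, 4.0, 8.0)
        spec = compute_psd(out)
        total = spec.total_power().sum()
        # measure over a window just wide enough to absorb the filter's
        # transition skirts and spectral bin edges
        inband = spec.band_power(BandDefinition("theta+", "θ+", 3.0, 9.5)).sum()
        assert inband / total > 0.85

    def test_filtering_is_linear(self):
        x = np.random.default_rng(1).normal(0, 1, (2, 2000))
        rec = make_recording(x)
        scaled = make_recording(3.5 * x)
        np.testing.assert_allclose(
            apply_bandpass(scaled, 4, 8).samples,
            3.5 * apply_bandpass(rec, 4, 8).samples,
            atol=1e-10,
        )


class TestBlinkDetection:
    def test_zero_signal_all_false(self):
        rec = make_recording(np.zeros((4, 2000)), names=("Fp1", "Fp2", "F3", "F4"))
        assert not detect_blinks(rec).any()

    def test_clean_eeg_low_false_positive_rate(self):
        rec, _ = generate_coupled_eeg(CouplingSpec(coupling={"α": 0.2}), duration_s=40, seed=7)
        mask = detect_blinks(rec)
        assert mask[0].mean() < 0.01

    def test_injected_blinks_are_recovered(self):
        rec, _ = generate_coupled_eeg(CouplingSpec(coupling={"α": 0.2}), duration_s=60, seed=3)
        dirty, truth = inject_artifacts(rec, blink_rate_target=0.05, seed=11)
        mask = detect_blinks(dirty)
        hits = sum(mask[0, s:e].any() for s, e in truth["blinks"])
        assert hits >= 0.8 * len(truth["blinks"])

    def test_missing_frontal_channels_rejected(self):
        rec = make_recording(np.zeros((2, 500)), names=("O1", "O2"))
        with pytest.raises(ValueError):
            detect_blinks(rec)


class TestPSD:
    def test_sine_peak_in_every_window(self):
        rec = make_recording(sine(10.0, duration_s=6))
        spec = compute_psd(rec)
        for w in range(spec.n_windows):
            assert spec.freq_bins[np.argmax(spec.values[0, w])] == pytest.approx(10.0)

    def test_white_noise_parseval(self, rng):
        x = rng.normal(0, 2.0, int(30 * FS))
        spec = compute_psd(make_recording(x))
        integrated = np.trapezoid(spec.values[0], spec.freq_bins, axis=-1).mean()
        assert integrated == pytest.approx(4.0, rel=0.2)

    def test_zero_signal_zero_spectrogram(self):
        spec = compute_psd(make_recording(np.zeros(2000)))
        assert np.nanmax(spec.values) == 0.0

    def test_nonnegative_for_arbitrary_input(self, rng):
        spec = compute_psd(make_recording(rng.normal(0, 5, (3, 1500))))
        assert np.nanmin(spec.values) >= 0.0

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(make_recording(np.zeros(100)), window_sec=1.0)

    def test_heavily_masked_windows_dropped(self):
        rec = make_recording(sine(10.0, duration_s=4))
        rec.artifact_mask[0, :300] = True  # >25% of the first 1 s window
        spec = compute_psd(rec)
        assert np.isnan(spec.values[0, 0]).all()
        assert not np.isnan(spec.values[0, -1]).any()


class TestOutlierRemoval:
    def test_constant_series_unchanged(self):
        cleaned, removed = remove_outliers(np.array([1.0, 1.0, 1.0, 1.0]))
        np.testing.assert_array_equal(cleaned, [1, 1, 1, 1])
        assert removed.size == 0

    def test_gross_outlier_removed(self, rng):
        x = np.concatenate([rng.normal(0, 1, 100), [50.0]])
        cleaned, removed = remove_outliers(x)
        # oracle: direct mean/SD computation
        assert np.abs(50.0 - x.mean()) > 3 * x.std()
        assert 100 in removed
        assert 50.0 not in cleaned

    def test_moderate_extreme_survives(self):
        # [0,0,0,100]: the outlier inflates the SD enough to shield itself
        cleaned, removed = remove_outliers(np.array([0.0, 0.0, 0.0, 100.0]))
        np.testing.assert_array_equal(cleaned, [0, 0, 0, 100])
        assert removed.size == 0

    def test_single_pass_convention(self, rng):
        # the rule uses the statistics of the *input* series exactly once
        x = np.concatenate([rng.normal(0, 1, 50), [30.0, 8.0]])
        cleaned, removed = remove_outliers(x)
        expected = np.abs(x - x.mean()) > 3 * x.std()
        np.testing.assert_array_equal(np.flatnonzero(expected), removed)
        # a second pass may remove more; the operation itself never iterates
        assert remove_outliers(cleaned)[0].size <= cleaned.size

    def test_order_preserved(self):
        x = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
        cleaned, _ = remove_outliers(x)
        np.testing.assert_array_equal(cleaned, x)
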