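"""Synthetic HbO generator: component spectra, amplitudes, determinism."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from nirscast import (ComponentSpec, DatasetSpec, HrfSpec, generate_ar_noise,
                      generate_dataset, generate_dhrf, generate_oscillation)
from nirscast.synthetic import DEFAULT_COMPONENTS, generate_record

FS = 8.138


class TestArNoise:
    def test_unit_variance_and_zero_mean(self):
        rng = np.random.default_rng(1)
        sig = generate_ar_noise(30, 4883, rng)
        assert abs(sig.samples.mean()) < 1e-12
        assert abs(sig.samples.var() - 1.0) < 1e-9   # normalized by construction

    def test_determinism_under_fixed_seed(self):
        a = generate_ar_noise(30, 1000, np.random.default_rng(7))
        b = generate_ar_noise(30, 1000, np.random.default_rng(7))
        assert np.array_equal(a.samples, b.samples)

    def test_stability_over_many_draws(self):
        # random partial autocorrelations in (-1/2, 1/2) must always give a
        # bounded realization
        for seed in range(20):
            sig = generate_ar_noise(30, 2000, np.random.default_rng(seed))
            assert np.all(np.isfinite(sig.samples))
            assert np.max(np.abs(sig.samples)) < 50

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_ar_noise(30, 30, np.random.default_rng(0))


class TestOscillation:
    def test_cardiac_periodogram_peak_in_band(self):
        spec = ComponentSpec("cardiac", 1.0, 0.1)
        sig = generate_oscillation(spec, 4883, FS, np.random.default_rng(3))
        f, p = sp_signal.periodogram(sig.samples, fs=FS)
        assert 0.9 <= f[np.argmax(p)] <= 1.1

    def test_degenerate_spec_gives_exact_sinusoid(self):
        spec = ComponentSpec("mayer", 0.1, 0.0, amp_low=1.0, amp_high=1.0)
        sig = generate_oscillation(spec, 1000, FS, np.random.default_rng(0))
        t = np.arange(1000) / FS
        # fit phase by least squares on the known frequency
        basis = np.column_stack([np.sin(2 * np.pi * 0.1 * t),
                                 np.cos(2 * np.pi * 0.1 * t)])
        resid = sig.samples - basis @ np.linalg.lstsq(basis, sig.samples,
                                                      rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-9
        assert abs(np.hypot(*np.linalg.lstsq(basis, sig.samples,
                                             rcond=None)[0]) - 1.0) < 1e-9

    def test_vlf_cycle_count_over_600s(self):
        spec = ComponentSpec("very_low_freq", 0.01, 0.001)
        n = int(round(600 * FS))
        for seed in range(5):
            sig = generate_oscillation(spec, n, FS, np.random.default_rng(seed))
            crossings = np.sum(np.diff(np.signbit(sig.samples)) != 0)
            assert 5.4 <= crossings / 2 <= 6.7


class TestDhrf:
    def test_unit_peak_scaling(self):
        spec = HrfSpec(task_onset_s=10.0)
        sig = generate_dhrf(spec, int(60 * FS), FS, amplitude=0.2)
        assert abs(sig.samples.max() - 0.2) < 1e-9

    def test_peak_later_than_10s_after_onset(self):
        spec = HrfSpec(task_onset_s=0.0)
        sig = generate_dhrf(spec, int(50 * FS), FS, amplitude=1.0)
        assert np.argmax(sig.samples) / FS > 10.0

    def test_zero_outside_support(self):
        spec = HrfSpec(task_onset_s=20.0)
        sig = generate_dhrf(spec, int(100 * FS), FS, amplitude=0.3)
        onset = int(round(20.0 * FS))
        end = onset + int(round(40.0 * FS))
        assert np.all(sig.samples[:onset] == 0)
        assert np.all(sig.samples[end:] == 0)

    def test_zero_amplitude_gives_zeros(self):
        sig = generate_dhrf(HrfSpec(task_onset_s=0.0), int(50 * FS), FS,
                            amplitude=0.0)
        assert np.all(sig.samples == 0)

    def test_overrunning_response_rejected(self):
        with pytest.raises(ValueError, match="past the record end"):
            generate_dhrf(HrfSpec(task_onset_s=30.0), int(40 * FS), FS,
                          amplitude=0.1)


class TestDataset:
    def test_counts_lengths_and_flags(self, small_dataset):
        assert len(small_dataset) == 10
        assert sum(r.has_dhrf for r in small_dataset) == 5
        spec = DatasetSpec(n_records=10, master_seed=42)
        for rec in small_dataset:
            assert rec.combined.n == spec.n_samples == 5208
            assert rec.combined.samples[0] == 0.0

    def test_bitwise_reproducibility(self, small_dataset):
        again = generate_dataset(DatasetSpec(n_records=10, master_seed=42))
        for a, b in zip(small_dataset, again):
            assert np.array_equal(a.combined.samples, b.combined.samples)
            assert a.has_dhrf == b.has_dhrf

    def test_combined_is_offset_sum_of_components(self, small_dataset):
        for rec in small_dataset:
            total = np.sum([c.samples for c in rec.components.values()], axis=0)
            diff = rec.combined.samples - total
            assert np.max(np.abs(diff - diff[0])) < 1e-12

    def test_amplitude_bounds(self, small_dataset):
        for rec in small_dataset:
            for name, comp in rec.components.items():
                if name == "dhrf":
                    assert 0.1 <= comp.samples.max() <= 0.35
                elif name != "baseline_ar":
                    amp = np.max(np.abs(comp.samples))
                    assert 0.0095 <= amp <= 0.0305
            assert 0.01 <= rec.draws["baseline_ar_amp"] <= 0.03

    def test_single_with_dhrf_for_two_records(self):
        ds = generate_dataset(DatasetSpec(n_records=2, master_seed=0))
        assert sum(r.has_dhrf for r in ds) == 1

    def test_averaged_spectra_show_component_peaks(self):
        ds = generate_dataset(DatasetSpec(n_records=12, master_seed=9,
                                          fraction_with_dhrf=0.0))
        bands = {"cardiac": (0.9, 1.1), "respiratory": (0.24, 0.26),
                 "mayer": (0.09, 0.11), "vlf": (0.009, 0.011)}
        f = None
        spectra = {k: [] for k in bands}
        for rec in ds:
            for name in bands:
                f, p = sp_signal.periodogram(rec.components[name].samples, fs=FS)
                spectra[name].append(p)
        for name, (lo, hi) in bands.items():
            mean_p = np.mean(spectra[name], axis=0)
            peak = f[np.argmax(mean_p)]
            assert lo <= peak <= hi, name

    def test_dhrf_placed_after_rest_period(self, small_dataset):
        rec = next(r for r in small_dataset if r.has_dhrf)
        d = rec.components["dhrf"].samples
        assert np.all(d[:rec.rest_samples] == 0)
        assert d[rec.rest_samples:].max() > 0


class TestZeroAmplitudeResponse:
    def test_zero_amplitude_record_equals_plain_noise_record(self):
        # a response of amplitude zero adds nothing: the combined trace is
        # bitwise the noise-only trace for the same seed, so the with/without
        # groups become statistically indistinguishable by construction
        spec = DatasetSpec(n_records=2, master_seed=3)
        hrf = HrfSpec(task_onset_s=600.0, amp_low=0.0, amp_high=0.0)
        with_zero = generate_record(spec, seed=123, with_dhrf=True, hrf=hrf)
        plain = generate_record(spec, seed=123, with_dhrf=False)
        assert np.array_equal(with_zero.combined.samples,
                              plain.combined.samples)
        assert np.all(with_zero.components["dhrf"].samples == 0)
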