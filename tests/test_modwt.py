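"""MODWT core: filter bank construction, transform, MRA, level selection.

The transform is checked against a brute-force O(n^2) evaluation of the
defining circular-convolution sums — the oracle is written directly from the
definition and shares no code with the implementation.
"""

import numpy as np
import pytest

from nirscast import (Signal1D, dyadic_band, make_filter_bank, modwt, mra,
                      select_level)

FS = 8.138


def periodize(filt, n):
    out = np.zeros(n)
    for l, v in enumerate(filt):
        out[l % n] += v
    return out


def direct_modwt_level(x, filt):
    """Brute-force W_{j,t} = sum_l h~o_{j,l} x_{(t-l) mod n}."""
    n = len(x)
    h = periodize(filt, n)
    return np.array([sum(h[l] * x[(t - l) % n] for l in range(n))
                     for t in range(n)])


class TestFilterBank:
    def test_level1_filters_are_rescaled_dwt_pair(self):
        bank = make_filter_bank("sym4", 1)
        assert len(bank.high_pass[0]) == 8
        assert abs(bank.high_pass[0].sum()) < 1e-10
        assert abs(bank.low_pass[0].sum() - 1.0) < 1e-10

    def test_haar_level1_values(self):
        bank = make_filter_bank("haar", 1)
        assert np.allclose(sorted(bank.low_pass[0]), [0.5, 0.5])
        assert np.allclose(sorted(bank.high_pass[0]), [-0.5, 0.5])

    def test_every_level_highpass_sums_to_zero(self):
        bank = make_filter_bank("sym4", 8)
        for j in range(8):
            assert abs(bank.high_pass[j].sum()) < 1e-10
            # equivalent filter length (2^j - 1)(L - 1) + 1
            assert len(bank.high_pass[j]) == (2 ** (j + 1) - 1) * 7 + 1

    def test_level8_gain_concentrates_in_dyadic_band(self):
        bank = make_filter_bank("sym4", 8)
        h = bank.high_pass[7]
        freqs = np.linspace(0, 0.5, 4096, endpoint=False)
        gain = np.abs(np.exp(-2j * np.pi * np.outer(freqs, np.arange(len(h))))
                      @ h) ** 2
        lo, hi = 2.0 ** -9, 2.0 ** -8        # cycles/sample
        inband = gain[(freqs >= lo) & (freqs <= hi)].sum()
        assert inband / gain.sum() > 0.55

    def test_unknown_wavelet_raises_with_name(self):
        with pytest.raises(ValueError, match="nosuchwavelet"):
            make_filter_bank("nosuchwavelet", 3)


class TestModwt:
    def test_constant_signal_goes_entirely_to_scaling(self):
        sig = Signal1D(np.full(64, 3.25), FS)
        coeffs = modwt(sig, make_filter_bank("sym4", 3))
        assert np.max(np.abs(coeffs.details)) < 1e-10
        assert np.allclose(coeffs.scaling, 3.25, atol=1e-10)

    def test_matches_direct_formula_on_arbitrary_length(self, rng):
        x = rng.normal(size=100)
        bank = make_filter_bank("sym4", 4)
        coeffs = modwt(Signal1D(x, FS), bank)
        for j in range(4):
            expected = direct_modwt_level(x, bank.high_pass[j])
            assert np.max(np.abs(coeffs.details[j] - expected)) < 1e-10
        expected_v = direct_modwt_level(x, bank.low_pass[3])
        assert np.max(np.abs(coeffs.scaling - expected_v)) < 1e-10

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=250)
        bank = make_filter_bank("sym4", 5)
        base = modwt(Signal1D(x, FS), bank)
        for k in (1, 17, 200):
            shifted = modwt(Signal1D(np.roll(x, k), FS), bank)
            assert np.max(np.abs(shifted.details
                                 - np.roll(base.details, k, axis=1))) < 1e-10
            assert np.max(np.abs(shifted.scaling
                                 - np.roll(base.scaling, k))) < 1e-10

    def test_excess_levels_warn_but_compute(self, rng):
        sig = Signal1D(rng.normal(size=64), FS)
        with pytest.warns(UserWarning, match="select_level"):
            coeffs = modwt(sig, make_filter_bank("sym4", 8))
        assert coeffs.details.shape == (8, 64)

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            Signal1D(np.array([0.0, np.nan, 1.0]), FS)


class TestMraAndInvariants:
    @pytest.mark.parametrize("n", [50, 100, 487, 512, 1000, 4883])
    def test_perfect_reconstruction_and_energy(self, n, rng):
        x = rng.normal(size=n)
        bank = make_filter_bank("sym4", select_level(n))
        coeffs = modwt(Signal1D(x, FS), bank)
        comps = mra(coeffs)
        rel = (np.linalg.norm(comps.reconstruct() - x) / np.linalg.norm(x))
        assert rel < 1e-8
        energy = np.sum(coeffs.details ** 2) + np.sum(coeffs.scaling ** 2)
        assert abs(energy - np.sum(x ** 2)) / np.sum(x ** 2) < 1e-6

    def test_fuzz_reconstruction_many_lengths(self, rng):
        for _ in range(40):
            n = int(rng.integers(50, 5000))
            x = rng.normal(size=n)
            comps = mra(modwt(Signal1D(x, FS), make_filter_bank("sym4",
                                                                select_level(n))))
            rel = np.linalg.norm(comps.reconstruct() - x) / np.linalg.norm(x)
            assert rel < 1e-8

    def test_constant_signal_mra(self):
        comps = mra(modwt(Signal1D(np.full(487, 2.0), FS),
                          make_filter_bank("sym4", 8)))
        assert np.max(np.abs(comps.details)) < 1e-10
        assert np.allclose(comps.approximation, 2.0, atol=1e-10)

    def test_slow_sinusoid_lands_in_level8(self):
        t = np.arange(4883) / FS
        sig = Signal1D(np.sin(2 * np.pi * 0.025 * t), FS)
        comps = mra(modwt(sig, make_filter_bank("sym4", 8)))
        energies = [np.sum(comps.details[j] ** 2) for j in range(8)]
        energies.append(np.sum(comps.approximation ** 2))
        assert int(np.argmax(energies)) == 7          # D_8
        lo, hi = dyadic_band(8, FS)
        assert lo < 0.025 < hi

    @pytest.mark.parametrize("level", [2, 3, 4, 5, 6, 7])
    def test_band_center_sinusoid_energy_fraction(self, level):
        lo, hi = dyadic_band(level, FS)
        f = np.sqrt(lo * hi)
        t = np.arange(4883) / FS
        comps = mra(modwt(Signal1D(np.sin(2 * np.pi * f * t), FS),
                          make_filter_bank("sym4", 8)))
        total = np.sum(comps.details ** 2) + np.sum(comps.approximation ** 2)
        assert np.sum(comps.details[level - 1] ** 2) / total > 0.6

    def test_component_indexing_convention(self, rng):
        comps = mra(modwt(Signal1D(rng.normal(size=200), FS),
                          make_filter_bank("sym4", 4)))
        assert np.shares_memory(comps.component(1), comps.details[0])
        assert np.shares_memory(comps.component(5), comps.approximation)
        with pytest.raises(ValueError):
            comps.component(6)


class TestSelectLevel:
    @pytest.mark.parametrize("n,expected", [
        (487, 8),       # 60 s at 8.138 Hz
        (256, 7),       # exact power of two: strictly below
        (4883, 12),
        (2, 0),
        (3, 1),
    ])
    def test_rule(self, n, expected):
        assert select_level(n) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            select_level(1)
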