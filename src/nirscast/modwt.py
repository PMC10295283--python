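"""Maximal overlap discrete wavelet transform (MODWT) and its multiresolution analysis.

The MODWT is the non-decimated, shift-equivariant relative of the DWT.  It is
defined for signals of arbitrary length n via circular filtering: at level j

    W_{j,t} = sum_l  h~o_{j,l} X_{(t-l) mod n},
    V_{J,t} = sum_l  g~o_{J,l} X_{(t-l) mod n},

where h~_j = h_j / 2^{j/2} and g~_j = g_j / 2^{j/2} are the rescaled level-j
DWT filter pair and the superscript "o" denotes periodization to length n.
The multiresolution analysis (MRA) inverts each level by circular
cross-correlation with the same filter, giving additive components

    X = D_1 + ... + D_J + A_J.

All convolutions here are evaluated exactly (to FFT round-off) in the Fourier
domain with the periodized equivalent filters, which is a literal — but fast —
evaluation of the defining sums.  sym4 is the default mother wavelet: its shape
resembles the canonical hemodynamic response, which is why it is preferred for
hemoglobin time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .signal import Signal1D

__all__ = [
    "ModwtFilterBank",
    "ModwtCoefficients",
    "MraComponents",
    "make_filter_bank",
    "modwt",
    "mra",
    "select_level",
    "dyadic_band",
]


@dataclass(frozen=True)
class ModwtFilterBank:
    """Per-level MODWT equivalent filters derived from one mother wavelet.

    ``high_pass[j-1]`` / ``low_pass[j-1]`` are the level-j equivalent wavelet
    and scaling filters h~_j, g~_j (not yet periodized).  Level 1 equals the
    base DWT pair divided by sqrt(2); level j is generated by the standard
    cascade (base filter upsampled by 2^{j-1}, convolved with the level-(j-1)
    scaling filter).
    """

    wavelet_name: str
    levels: int
    high_pass: tuple[np.ndarray, ...]
    low_pass: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class ModwtCoefficients:
    """MODWT wavelet coefficients W_1..W_J (rows of ``details``) plus scaling V_J.

    Every row has the length of the analyzed signal — the transform is
    non-decimated — and the energy identity
    ||X||^2 = sum_j ||W_j||^2 + ||V_J||^2 holds.
    """

    details: np.ndarray        # shape (J, n)
    scaling: np.ndarray        # shape (n,)
    bank: ModwtFilterBank
    n: int

    @property
    def levels(self) -> int:
        return self.details.shape[0]


@dataclass(frozen=True)
class MraComponents:
    """Additive MRA components: J details D_j plus the approximation A_J.

    ``details`` has shape (J, n); ``approximation`` has shape (n,).  Their
    pointwise sum reconstructs the analyzed signal.  In the five-band
    nomenclature used downstream, "wavelet j" for j <= J means D_j and
    "wavelet J+1" means A_J (e.g. wavelet 9 = A_8 after an 8-level transform).
    """

    details: np.ndarray
    approximation: np.ndarray

    @property
    def levels(self) -> int:
        return self.details.shape[0]

    def component(self, wavelet_index: int) -> np.ndarray:
        """Return D_j for 1 <= j <= J, or A_J for j = J + 1."""
        j = int(wavelet_index)
        if 1 <= j <= self.levels:
            return self.details[j - 1]
        if j == self.levels + 1:
            return self.approximation
        raise ValueError(f"wavelet index {wavelet_index} outside 1..{self.levels + 1}")

    def reconstruct(self) -> np.ndarray:
        return self.details.sum(axis=0) + self.approximation


def _base_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        w = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet name: {wavelet_name!r}") from exc
    if not w.orthogonal:
        raise ValueError(f"wavelet {wavelet_name!r} is not orthogonal")
    # MODWT rescaling: level-1 filters are the DWT pair divided by sqrt(2),
    # so the scaling filter sums to 1 and the wavelet filter to 0.
    g = np.asarray(w.dec_lo, dtype=float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float) / np.sqrt(2.0)
    return h, g


def _upsample(filt: np.ndarray, factor: int) -> np.ndarray:
    """Insert factor-1 zeros between taps."""
    if factor == 1:
        return filt
    out = np.zeros((len(filt) - 1) * factor + 1)
    out[::factor] = filt
    return out


def make_filter_bank(wavelet_name: str = "sym4", levels: int = 8) -> ModwtFilterBank:
    """Build per-level MODWT equivalent filters for an orthogonal wavelet.

    The level-j wavelet filter has (2^j - 1)(L - 1) + 1 taps (L = base filter
    length), sums to 0, and its squared gain concentrates in the dyadic band
    [fs / 2^{j+1}, fs / 2^j].
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h1, g1 = _base_filters(wavelet_name)
    highs = [h1]
    lows = [g1]
    for j in range(2, levels + 1):
        up = 2 ** (j - 1)
        highs.append(np.convolve(_upsample(h1, up), lows[-1]))
        lows.append(np.convolve(_upsample(g1, up), lows[-1]))
    return ModwtFilterBank(wavelet_name, levels, tuple(highs), tuple(lows))


def _periodize(filt: np.ndarray, n: int) -> np.ndarray:
    """Wrap a filter to length n (sum taps with equal index mod n)."""
    out = np.zeros(n)
    np.add.at(out, np.arange(len(filt)) % n, filt)
    return out


def select_level(n: int) -> int:
    """Decomposition-level rule: the largest integer strictly below log2(n).

    A 60-s segment at 8.138 Hz has 487.8 samples, hence level 8.  Exact powers
    of two return the exponent minus one.
    """
    n = int(n)
    if n < 2:
        raise ValueError("need at least 2 samples to select a level")
    j = n.bit_length() - 1          # floor(log2 n)
    if n == (1 << j):               # log2(n) integral -> strictly below
        return j - 1
    return j


def dyadic_band(level: int, fs: float) -> tuple[float, float]:
    """Nominal passband of detail D_level: [fs / 2^{level+1}, fs / 2^level] Hz.

    At fs = 8.138 Hz, D_8 covers [0.0159, 0.0318] Hz and the approximation A_8
    everything below 0.0159 Hz.
    """
    return fs / 2 ** (level + 1), fs / 2 ** level


def modwt(signal: Signal1D, bank: ModwtFilterBank) -> ModwtCoefficients:
    """MODWT of a signal: circular convolution with the periodized filters.

    Levels beyond the ``select_level`` rule for this length are legal (the
    transform stays invertible) but emit a warning, since those scales wrap
    around the record more than once.
    """
    x = signal.samples
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for a MODWT")
    J = bank.levels
    if J > select_level(n):
        warnings.warn(
            f"decomposition level {J} exceeds select_level({n}) = {select_level(n)}",
            stacklevel=2,
        )
    fx = np.fft.rfft(x)
    details = np.empty((J, n))
    for j in range(J):
        fh = np.fft.rfft(_periodize(bank.high_pass[j], n))
        details[j] = np.fft.irfft(fh * fx, n)
    fg = np.fft.rfft(_periodize(bank.low_pass[J - 1], n))
    scaling = np.fft.irfft(fg * fx, n)
    return ModwtCoefficients(details=details, scaling=scaling, bank=bank, n=n)


def mra(coeffs: ModwtCoefficients) -> MraComponents:
    """Multiresolution analysis: invert each level by circular correlation.

    D_{j,t} = sum_l h~o_{j,l} W_{j,(t+l) mod n} and likewise A_J from V_J; the
    components add back to the analyzed signal exactly (to round-off).
    """
    bank = coeffs.bank
    n = coeffs.n
    J = coeffs.levels
    details = np.empty((J, n))
    for j in range(J):
        fh = np.fft.rfft(_periodize(bank.high_pass[j], n))
        details[j] = np.fft.irfft(np.conj(fh) * np.fft.rfft(coeffs.details[j]), n)
    fg = np.fft.rfft(_periodize(bank.low_pass[J - 1], n))
    approx = np.fft.irfft(np.conj(fg) * np.fft.rfft(coeffs.scaling), n)
    return MraComponents(details=details, approximation=approx)


def decompose(signal: Signal1D, levels: int = 8,
              wavelet_name: str = "sym4") -> MraComponents:
    """Convenience: filter bank + MODWT + MRA in one call."""
    bank = make_filter_bank(wavelet_name, levels)
    return mra(modwt(signal, bank))
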