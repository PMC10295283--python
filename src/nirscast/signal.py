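"""Uniformly sampled scalar time series — the currency passed between modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Signal1D:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        1-D array of finite values (length >= 2 for anything analyzable;
        single-sample signals are allowed as forecast outputs).
    fs
        Sampling rate in Hz, > 0.
    label
        Free-text description (channel name, component name, ...).
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ValueError("Signal1D needs at least 1 sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal1D samples must be finite")
        if not (self.fs > 0):
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def slice(self, start: int, stop: int, label: str | None = None) -> "Signal1D":
        """Sub-signal over sample indices [start, stop)."""
        return Signal1D(self.samples[start:stop], self.fs,
                        self.label if label is None else label)

    def with_samples(self, samples: np.ndarray) -> "Signal1D":
        return replace(self, samples=np.asarray(samples, dtype=float))


def seconds_to_samples(seconds: float, fs: float) -> int:
    """Convert a duration to a sample count (nearest integer).

    At fs = 8.138 Hz this maps the training-length conditions
    [600, 300, 150, 90, 60] s onto [4883, 2441, 1221, 732, 488] samples
    and a 30-s horizon onto 244 samples.
    """
    return int(round(seconds * fs))
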