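"""Synthetic HbO record generator with labeled ground-truth components.

Each record emulates a single-channel oxyhemoglobin trace at 8.138 Hz:

* a stable AR(30) baseline noise process (colored, zero-mean, then scaled),
* four band-limited physiological oscillations — cardiac (1 +/- 0.1 Hz),
  respiratory (0.25 +/- 0.01 Hz), Mayer wave (0.1 +/- 0.01 Hz) and a very
  low-frequency component (0.01 +/- 0.001 Hz) — each a constant-frequency
  sinusoid with random phase and amplitude in [0.01, 0.03],
* optionally a task-evoked hemodynamic response: a two-gamma kernel convolved
  with a 20-s task boxcar, unit-peak normalized, amplitude in [0.1, 0.35],
  placed immediately after a 600-s resting period.

The combined trace is the pointwise sum of the components, shifted so the
first sample is exactly zero.  The generator is fully deterministic given a
master seed; per-record seeds are spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import gamma as gamma_dist

from .signal import Signal1D, seconds_to_samples

__all__ = [
    "ComponentSpec",
    "HrfSpec",
    "DatasetSpec",
    "SyntheticRecord",
    "generate_ar_noise",
    "generate_oscillation",
    "generate_dhrf",
    "generate_record",
    "generate_dataset",
    "DEFAULT_COMPONENTS",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One band-limited oscillation: a constant-frequency random sinusoid."""

    kind: str                      # cardiac | respiratory | mayer | very_low_freq
    center_freq: float             # Hz
    freq_halfwidth: float          # Hz
    amp_low: float = 0.01          # a.u.
    amp_high: float = 0.03         # a.u.


DEFAULT_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("cardiac", 1.0, 0.1),
    ComponentSpec("respiratory", 0.25, 0.01),
    ComponentSpec("mayer", 0.1, 0.01),
    ComponentSpec("very_low_freq", 0.01, 0.001),
)


@dataclass(frozen=True)
class HrfSpec:
    """Two-gamma task response: kernel (x) boxcar, unit peak, random amplitude.

    Canonical kernel parameters: response peak ~6 s, undershoot ~16 s,
    unit dispersions, undershoot 1/6 of the peak.
    """

    task_onset_s: float
    task_duration_s: float = 20.0
    post_rest_s: float = 20.0
    amp_low: float = 0.1
    amp_high: float = 0.35
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0


@dataclass(frozen=True)
class DatasetSpec:
    """Study-level generation parameters (defaults = the validation protocol)."""

    n_records: int = 1000
    fraction_with_dhrf: float = 0.5
    fs: float = 8.138
    rest_duration_s: float = 600.0
    task_window_s: float = 40.0
    master_seed: int = 0
    ar_order: int = 30

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not 0.0 <= self.fraction_with_dhrf <= 1.0:
            raise ValueError("fraction_with_dhrf must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return seconds_to_samples(self.rest_duration_s + self.task_window_s, self.fs)

    @property
    def rest_samples(self) -> int:
        return seconds_to_samples(self.rest_duration_s, self.fs)


@dataclass
class SyntheticRecord:
    """A generated trace plus its ground-truth components and draw metadata."""

    combined: Signal1D
    components: dict[str, Signal1D]
    has_dhrf: bool
    seed: int
    rest_samples: int
    draws: dict[str, float] = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return self.combined.fs


def _pacf_to_ar(pacf: np.ndarray) -> np.ndarray:
    """Levinson–Durbin map from partial autocorrelations to AR coefficients.

    Any |pacf| < 1 yields a stationary (stable) AR process, which is why the
    coefficients are drawn in this parameterization.
    """
    phi = np.zeros(0)
    for k, r in enumerate(pacf, start=1):
        prev = phi
        phi = np.empty(k)
        phi[k - 1] = r
        if k > 1:
            phi[: k - 1] = prev - r * prev[::-1]
    return phi


def generate_ar_noise(order: int, n: int, rng: np.random.Generator) -> Signal1D:
    """Stable AR(order) noise, zero-mean and normalized to unit sample variance.

    Partial autocorrelations are drawn uniformly in (-0.5, 0.5) and mapped to
    AR coefficients via Levinson–Durbin, guaranteeing stationarity by
    construction.  A burn-in of max(500, 10*order) samples removes the
    transient.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= order:
        raise ValueError("need n > order samples")
    pacf = rng.uniform(-0.5, 0.5, size=order)
    phi = _pacf_to_ar(pacf)
    burn = max(500, 10 * order)
    innov = rng.standard_normal(n + burn)
    x = sp_signal.lfilter([1.0], np.concatenate(([1.0], -phi)), innov)[burn:]
    x = x - x.mean()
    x /= x.std()
    return Signal1D(x, fs=1.0, label="ar_noise")


def generate_oscillation(spec: ComponentSpec, n: int, fs: float,
                         rng: np.random.Generator) -> Signal1D:
    """Sinusoid with frequency, phase, amplitude drawn once for the record."""
    freq = rng.uniform(spec.center_freq - spec.freq_halfwidth,
                       spec.center_freq + spec.freq_halfwidth)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp = rng.uniform(spec.amp_low, spec.amp_high)
    t = np.arange(n) / fs
    return Signal1D(amp * np.sin(2.0 * np.pi * freq * t + phase), fs, spec.kind)


def two_gamma_kernel(t: np.ndarray, spec: HrfSpec) -> np.ndarray:
    """Difference of two gamma densities: positive peak minus late undershoot."""
    peak = gamma_dist.pdf(t, spec.peak_delay_s / spec.peak_dispersion,
                          scale=spec.peak_dispersion)
    under = gamma_dist.pdf(t, spec.undershoot_delay_s / spec.undershoot_dispersion,
                           scale=spec.undershoot_dispersion)
    return peak - spec.undershoot_ratio * under


def generate_dhrf(spec: HrfSpec, n: int, fs: float,
                  rng: np.random.Generator | None = None,
                  amplitude: float | None = None) -> Signal1D:
    """Task-evoked response: two-gamma kernel (x) task boxcar, unit peak.

    Zero outside [onset, onset + task + post-rest]; the amplitude is drawn
    uniformly in [amp_low, amp_high] unless given explicitly.
    """
    support_s = spec.task_duration_s + spec.post_rest_s
    onset = seconds_to_samples(spec.task_onset_s, fs)
    width = seconds_to_samples(support_s, fs)
    # sample-count rounding may overshoot the record end by < 1 sample
    if onset + width > n + 1:
        raise ValueError("hemodynamic response extends past the record end")
    width = min(width, n - onset)
    if amplitude is None:
        if rng is None:
            raise ValueError("need rng or an explicit amplitude")
        amplitude = rng.uniform(spec.amp_low, spec.amp_high)
    t = np.arange(width) / fs
    kernel = two_gamma_kernel(t, spec)
    boxcar = (t < spec.task_duration_s).astype(float)
    resp = np.convolve(boxcar, kernel)[:width]
    if amplitude != 0.0:
        resp = resp / np.max(resp) * amplitude
    else:
        resp = np.zeros_like(resp)
    out = np.zeros(n)
    out[onset:onset + width] = resp
    return Signal1D(out, fs, "dhrf")


def generate_record(spec: DatasetSpec, seed: int, with_dhrf: bool,
                    components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS,
                    hrf: HrfSpec | None = None,
                    baseline_amp_low: float = 0.01,
                    baseline_amp_high: float = 0.03) -> SyntheticRecord:
    """One labeled record: AR baseline + oscillations (+ optional response).

    The AR baseline, like the four oscillations, receives an amplitude drawn
    in [0.01, 0.03] so that all five noise signals share the stated range.
    """
    rng = np.random.default_rng(seed)
    n, fs = spec.n_samples, spec.fs
    draws: dict[str, float] = {}

    ar_amp = rng.uniform(baseline_amp_low, baseline_amp_high)
    ar = generate_ar_noise(spec.ar_order, n, rng)
    parts = {"baseline_ar": Signal1D(ar_amp * ar.samples, fs, "baseline_ar")}
    draws["baseline_ar_amp"] = ar_amp

    short = {"cardiac": "cardiac", "respiratory": "respiratory",
             "mayer": "mayer", "very_low_freq": "vlf"}
    for comp in components:
        osc = generate_oscillation(comp, n, fs, rng)
        name = short.get(comp.kind, comp.kind)
        parts[name] = Signal1D(osc.samples, fs, name)

    if with_dhrf:
        if hrf is None:
            hrf = HrfSpec(task_onset_s=spec.rest_duration_s)
        amp = rng.uniform(hrf.amp_low, hrf.amp_high)
        parts["dhrf"] = generate_dhrf(hrf, n, fs, amplitude=amp)
        draws["dhrf_amp"] = amp

    total = np.sum([p.samples for p in parts.values()], axis=0)
    combined = Signal1D(total - total[0], fs, "combined")
    return SyntheticRecord(combined=combined, components=parts,
                           has_dhrf=with_dhrf, seed=seed,
                           rest_samples=spec.rest_samples, draws=draws)


def generate_dataset(spec: DatasetSpec) -> list[SyntheticRecord]:
    """Generate the full labeled dataset described by ``spec``.

    Exactly round(fraction_with_dhrf * n_records) records carry a response;
    which ones is decided by a seeded shuffle, and each record's own seed is
    spawned deterministically from the master seed, so regeneration with the
    same spec is bitwise identical.
    """
    master = np.random.SeedSequence(spec.master_seed)
    seeds = [int(s) & 0x7FFFFFFF for s in master.generate_state(spec.n_records)]
    n_with = int(round(spec.fraction_with_dhrf * spec.n_records))
    order = np.random.default_rng(master.generate_state(1, dtype=np.uint64)[0]
                                  ).permutation(spec.n_records)
    with_flags = np.zeros(spec.n_records, dtype=bool)
    with_flags[order[:n_with]] = True
    return [generate_record(spec, seeds[i], bool(with_flags[i]))
            for i in range(spec.n_records)]
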