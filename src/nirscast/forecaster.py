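"""Per-wavelet LSTM forecasting: windowing, normalization, training, recursion.

One forecaster is bound to one wavelet component (detail D_5..D_8 or
approximation A_8, i.e. "wavelets 5-9").  It is trained on next-sample
targets built from z-scored resting-state data and extends the series into
the task window by recursive one-step prediction: each predicted sample is
appended to the context and the window re-run.  The 30-s horizon at 8.138 Hz
is 244 samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline

from .nn import Adam, SequenceRegressor
from .signal import Signal1D

__all__ = [
    "ForecasterConfig",
    "NormalizationParams",
    "TrainedForecaster",
    "ForecastResult",
    "make_training_windows",
    "train_forecaster",
    "train_pooled_forecaster",
    "forecast",
    "forecast_batch",
    "persistence_forecast",
    "save_forecaster",
    "load_forecaster",
    "DEFAULT_HORIZON",
]

DEFAULT_HORIZON = 244          # 30 s x 8.138 Hz


@dataclass(frozen=True)
class ForecasterConfig:
    """Training hyperparameters.

    Defaults follow the stacked architecture used throughout: three LSTM
    layers of [128, 64, 32] hidden units, dropout 0.2 between layers, Adam
    with minibatch 128 for up to 100 epochs.  ``lookback`` (64 samples,
    ~7.9 s) sets the input window; ``window_stride`` subsamples the
    overlapping training windows (they overlap by lookback-1 samples, so a
    stride > 1 mostly removes redundancy and bounds the work per epoch).
    """

    hidden_units: tuple[int, ...] = (128, 64, 32)
    dropout: float = 0.2
    max_epochs: int = 100
    minibatch: int = 128
    lookback: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    window_stride: int = 1
    dilation: int = 1

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden_units must all be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lookback < 1 or self.window_stride < 1 or self.dilation < 1:
            raise ValueError("lookback, window_stride, dilation must be >= 1")

    @property
    def context_samples(self) -> int:
        """Full-rate samples one input window spans: lookback x dilation."""
        return self.lookback * self.dilation


@dataclass(frozen=True)
class NormalizationParams:
    """z-score parameters; a constant series gets scale 1 so the map stays invertible."""

    center: float
    scale: float

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "NormalizationParams":
        x = np.asarray(x, dtype=float)
        sd = float(x.std())
        return cls(center=float(x.mean()), scale=sd if sd > 0.0 else 1.0)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.scale + self.center


@dataclass
class TrainedForecaster:
    """A trained network plus the normalization it expects and its level binding."""

    config: ForecasterConfig
    norm: NormalizationParams
    wavelet_level: int
    model: SequenceRegressor
    loss_history: list[float] = field(default_factory=list)
    initial_loss: float = float("nan")


@dataclass
class ForecastResult:
    predicted: Signal1D
    horizon_samples: int
    context_end_index: int


def make_training_windows(samples: np.ndarray, lookback: int, stride: int = 1,
                          dilation: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Supervised next-sample pairs: X[i] = x[i:i+lookback], y[i] = x[i+lookback].

    With ``dilation`` d > 1 the window reads every d-th sample
    (X[i] = x[i : i + lookback*d : d], y[i] = x[i + lookback*d]): the model
    then works at the component's natural, decimated rate, which is lossless
    for band-limited wavelet components as long as the decimated rate stays
    above twice the band's upper edge.  Windows still slide at full rate
    (``stride`` applies on top), so every phase of the decimated grid is
    trained.
    """
    x = np.asarray(samples, dtype=float).ravel()
    span = lookback * dilation
    if x.size < span + 1:
        raise ValueError(
            f"series of length {x.size} too short for lookback {lookback} "
            f"x dilation {dilation}")
    W = sliding_window_view(x, span + 1)[::stride]
    return W[:, :-1:dilation][:, :lookback], W[:, -1]


def _fit(X: np.ndarray, y: np.ndarray, config: ForecasterConfig
         ) -> tuple[SequenceRegressor, list[float], float]:
    """Adam / MSE minibatch training on (N, lookback) windows."""
    model = SequenceRegressor(hidden_units=tuple(config.hidden_units),
                              dropout=config.dropout, seed=config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    N = X.shape[0]
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    yf = np.ascontiguousarray(y, dtype=np.float32)

    def batch_input(idx: np.ndarray) -> np.ndarray:
        # (B, lookback) -> (T, B, 1)
        return np.ascontiguousarray(Xf[idx].T)[:, :, None]

    probe = min(N, 2048)
    initial = float(np.mean((model.predict(batch_input(np.arange(probe)))
                             - yf[:probe]) ** 2))
    history: list[float] = []
    bs = config.minibatch
    for _ in range(config.max_epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N - bs + 1, bs):
            idx = order[start:start + bs]
            pred = model.forward(batch_input(idx), train=True)
            err = pred - yf[idx]
            losses.append(float(np.mean(err ** 2)))
            grads = model.backward(2.0 * err / err.size)
            opt.step(grads)
        if not losses:                      # fewer samples than one minibatch
            pred = model.forward(batch_input(np.arange(N)), train=True)
            err = pred - yf
            losses.append(float(np.mean(err ** 2)))
            grads = model.backward(2.0 * err / err.size)
            opt.step(grads)
        history.append(float(np.mean(losses)))
    return model, history, initial


def train_forecaster(series: Signal1D, config: ForecasterConfig,
                     wavelet_level: int = 0) -> TrainedForecaster:
    """Train on a single series; normalization parameters come from that series."""
    norm = NormalizationParams.from_samples(series.samples)
    X, y = make_training_windows(norm.normalize(series.samples),
                                 config.lookback, config.window_stride,
                                 config.dilation)
    model, history, initial = _fit(X, y, config)
    return TrainedForecaster(config=config, norm=norm,
                             wavelet_level=wavelet_level, model=model,
                             loss_history=history, initial_loss=initial)


def train_pooled_forecaster(series_list: list[np.ndarray | Signal1D],
                            config: ForecasterConfig,
                            wavelet_level: int = 0) -> TrainedForecaster:
    """Train one network on many series pooled, each z-scored by its own stats.

    The returned model works in normalized units (identity NormalizationParams);
    callers normalize each new context with that record's own parameters.
    """
    Xs, ys = [], []
    for s in series_list:
        x = s.samples if isinstance(s, Signal1D) else np.asarray(s, dtype=float)
        local = NormalizationParams.from_samples(x)
        X, y = make_training_windows(local.normalize(x), config.lookback,
                                     config.window_stride, config.dilation)
        Xs.append(X)
        ys.append(y)
    model, history, initial = _fit(np.concatenate(Xs), np.concatenate(ys), config)
    return TrainedForecaster(config=config, norm=NormalizationParams(0.0, 1.0),
                             wavelet_level=wavelet_level, model=model,
                             loss_history=history, initial_loss=initial)


def _recurse(model: TrainedForecaster, windows: np.ndarray,
             steps: int) -> np.ndarray:
    """Plain recursive one-step prediction in the model's (dilated) domain.

    ``windows``: (B, lookback); each prediction is appended and the window
    shifted.  Returns (B, steps).
    """
    window = np.asarray(windows, dtype=np.float32).copy()
    out = np.empty((window.shape[0], steps), dtype=float)
    for k in range(steps):
        x = np.ascontiguousarray(window.T)[:, :, None]
        pred = model.model.predict(x)
        out[:, k] = pred
        window[:, :-1] = window[:, 1:]
        window[:, -1] = pred
    return out


def forecast_batch(model: TrainedForecaster, contexts: np.ndarray,
                   horizon: int) -> np.ndarray:
    """Recursive one-step forecasts for several normalized contexts at once.

    ``contexts``: (B, >= lookback x dilation) consecutive full-rate samples in
    normalized units; returns (B, horizon) full-rate values.  For dilation 1
    each prediction is simply appended to the context window.  For dilation
    d > 1 the recursion runs on the decimated grid; forecasts from up to four
    interleaved grid phases are interpolated back to full rate (cubic spline
    anchored at the context end) and averaged.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    cfg = model.config
    lb, d = cfg.lookback, cfg.dilation
    contexts = np.asarray(contexts, dtype=np.float32)
    if contexts.ndim == 1:
        contexts = contexts[None, :]
    if contexts.shape[1] < lb * d:
        raise ValueError(
            f"context shorter than lookback {lb} x dilation {d}")
    B = contexts.shape[0]
    if d == 1:
        return _recurse(model, contexts[:, -lb:], horizon)

    n_phases = min(4, d)
    steps = int(np.ceil((horizon + d) / d)) + 1
    # stack (phase, record) windows into one recursion batch
    windows = np.empty((n_phases, B, lb), dtype=np.float32)
    n_ctx = contexts.shape[1]
    for p in range(n_phases):
        end = n_ctx - 1 - p
        idx = end - d * np.arange(lb)[::-1]
        windows[p] = contexts[:, idx]
    z = _recurse(model, windows.reshape(n_phases * B, lb), steps)
    z = z.reshape(n_phases, B, steps)

    target_t = np.arange(1, horizon + 1, dtype=float)   # past context end
    out = np.zeros((B, horizon), dtype=float)
    for p in range(n_phases):
        # anchor at the phase's last observed sample, then predicted knots
        knots_t = np.concatenate(([-float(p)],
                                  -p + d * np.arange(1, steps + 1, dtype=float)))
        knots_v = np.concatenate(
            [contexts[:, n_ctx - 1 - p][:, None], z[p]], axis=1)
        spline = CubicSpline(knots_t, knots_v, axis=1)
        out += spline(target_t)
    return out / n_phases


def forecast(model: TrainedForecaster, context: Signal1D,
             horizon: int = DEFAULT_HORIZON,
             norm: NormalizationParams | None = None) -> ForecastResult:
    """Forecast ``horizon`` samples past the end of ``context`` (original units)."""
    norm = model.norm if norm is None else norm
    ctx = norm.normalize(context.samples)
    pred = forecast_batch(model, ctx[None, :], horizon)[0]
    predicted = Signal1D(norm.denormalize(pred), context.fs,
                         f"forecast_w{model.wavelet_level}")
    return ForecastResult(predicted=predicted, horizon_samples=horizon,
                          context_end_index=context.n)


def persistence_forecast(context: np.ndarray, horizon: int) -> np.ndarray:
    """Last-value-carried-forward baseline, same units as the context."""
    return np.full(horizon, float(np.asarray(context).ravel()[-1]))


def save_forecaster(model: TrainedForecaster, path: str | Path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with config and normalization."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.model.state_arrays())
    manifest = {
        "config": asdict(model.config),
        "norm": {"center": model.norm.center, "scale": model.norm.scale},
        "wavelet_level": model.wavelet_level,
        "loss_history": model.loss_history,
        "initial_loss": model.initial_loss,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_forecaster(path: str | Path) -> TrainedForecaster:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_d = manifest["config"]
    cfg_d["hidden_units"] = tuple(cfg_d["hidden_units"])
    config = ForecasterConfig(**cfg_d)
    model = SequenceRegressor(hidden_units=config.hidden_units,
                              dropout=config.dropout, seed=config.seed)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state({k: data[k] for k in data.files})
    return TrainedForecaster(
        config=config,
        norm=NormalizationParams(**manifest["norm"]),
        wavelet_level=manifest["wavelet_level"],
        model=model,
        loss_history=list(manifest.get("loss_history", [])),
        initial_loss=manifest.get("initial_loss", float("nan")),
    )
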