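"""End-to-end orchestration: decompose -> train -> predict -> subtract.

The method extracts low-frequency wavelet components ("wavelets 5-9": details
D_5..D_8 plus approximation A_8 of an 8-level sym4 MODWT) from resting-state
data, trains one LSTM forecaster per component on the training records
pooled, extends each component 244 samples (30 s) into the task window, and
subtracts the predicted noise from the measured task segment.  Prediction
errors are scored in normalized units against the component of the *full*
record (rest + task window), so a task-evoked response that leaks into a
component shows up as excess prediction error — the detection signal.

Six data-segmentation conditions control how much resting data feeds the
decomposition and the network: (600, 300), (600, 600), (300, 300),
(150, 150), (90, 90) and (60, 60) seconds of (MODWT, LSTM training) data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .modwt import (MraComponents, make_filter_bank, modwt as modwt_transform,
                    mra as modwt_mra)
from .evaluation import mae, rmse, summarize_groups, windowed_errors
from .forecaster import (ForecasterConfig, NormalizationParams,
                         TrainedForecaster, forecast_batch,
                         train_pooled_forecaster, DEFAULT_HORIZON)
from .signal import Signal1D, seconds_to_samples
from .synthetic import SyntheticRecord

__all__ = [
    "SegmentationCondition",
    "DenoiseSpec",
    "ExperimentResult",
    "run_synthetic_experiment",
    "denoise_task_segment",
    "run_leave_one_out",
    "DEFAULT_LEVELS",
    "DECOMPOSITION_LEVELS",
]

log = logging.getLogger("nirscast")

DEFAULT_LEVELS: tuple[int, ...] = (5, 6, 7, 8, 9)
DECOMPOSITION_LEVELS = 8        # fixed across all segment lengths

_CONDITIONS: dict[int, tuple[float, float]] = {
    1: (600.0, 300.0),
    2: (600.0, 600.0),
    3: (300.0, 300.0),
    4: (150.0, 150.0),
    5: (90.0, 90.0),
    6: (60.0, 60.0),
}


@dataclass(frozen=True)
class SegmentationCondition:
    """How much resting data feeds the MODWT and the LSTM (seconds)."""

    id: int
    modwt_length_s: float
    lstm_train_length_s: float

    def __post_init__(self) -> None:
        if self.lstm_train_length_s > self.modwt_length_s:
            raise ValueError("LSTM training length cannot exceed MODWT length")

    @classmethod
    def from_id(cls, condition_id: int) -> "SegmentationCondition":
        try:
            m, l = _CONDITIONS[condition_id]
        except KeyError:
            raise ValueError(f"condition id must be 1..6, got {condition_id}")
        return cls(condition_id, m, l)

    def modwt_samples(self, fs: float) -> int:
        return seconds_to_samples(self.modwt_length_s, fs)

    def lstm_samples(self, fs: float) -> int:
        return seconds_to_samples(self.lstm_train_length_s, fs)


@dataclass(frozen=True)
class DenoiseSpec:
    """Which wavelet components are predicted and subtracted, and how far."""

    wavelet_levels: tuple[int, ...] = DEFAULT_LEVELS
    horizon_samples: int = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if not self.wavelet_levels:
            raise ValueError("need at least one wavelet level")


def _component(components: MraComponents, level: int) -> np.ndarray:
    """'Wavelet level' in the 1..J+1 convention (J+1 = approximation)."""
    return components.component(level)


def _auto_dilation(level: int, train_len: int, lookback: int) -> int:
    """Decimation factor for the forecaster of one wavelet level.

    Level j is band-limited below fs / 2^j, so its component can be read at
    1 / 2^{j-2} of the full rate (a 2x margin above the band's Nyquist
    requirement).  The factor is capped so an input window still fits well
    inside the training segment.
    """
    cap = max(1, (train_len - lookback) // lookback)
    return int(max(1, min(2 ** (level - 2), cap)))


def _level_config(config: ForecasterConfig, level: int, train_len: int,
                  n_series: int, max_train_windows: int) -> ForecasterConfig:
    """Per-level training configuration: seed offset, dilation, window stride."""
    d = _auto_dilation(level, train_len, config.lookback)
    per_series = max(1, train_len - config.lookback * d)
    stride = max(1, (per_series * n_series) // max_train_windows)
    return replace(config, seed=config.seed + 17 * level, dilation=d,
                   window_stride=max(stride, config.window_stride))


@dataclass
class ExperimentResult:
    """Per-record forecasts and references (normalized units) plus summaries."""

    condition: SegmentationCondition
    levels: tuple[int, ...]
    horizon: int
    errors: pd.DataFrame                 # record_id, wavelet_level, group, mae, rmse
    metrics: pd.DataFrame                # per-level group summary with Welch p
    predictions: dict[int, np.ndarray]   # level -> (n_test, horizon)
    references: dict[int, np.ndarray]    # level -> (n_test, horizon)
    norms: dict[int, list[NormalizationParams]]
    models: dict[int, TrainedForecaster]
    test_records: list[SyntheticRecord]
    split_seed: int = 0

    def windowed_summary(self, windows_s=(1, 3, 5, 10, 15, 30)) -> pd.DataFrame:
        """Cumulative windowed errors per record, summarized per (level, window)."""
        rows = []
        fs = self.test_records[0].fs
        for level in self.levels:
            for i, rec in enumerate(self.test_records):
                wdf = windowed_errors(self.references[level][i],
                                      self.predictions[level][i], fs, windows_s)
                for _, r in wdf.iterrows():
                    rows.append({
                        "record_id": i, "wavelet_level": level,
                        "group": "with_dhrf" if rec.has_dhrf else "without_dhrf",
                        "window_s": r["window_s"],
                        "mae": r["mae"], "rmse": r["rmse"],
                    })
        per_record = pd.DataFrame(rows)
        return summarize_groups(per_record, by=("wavelet_level", "window_s"))


def _stratified_split(dataset: list[SyntheticRecord], n_train: int, n_test: int,
                      seed: int) -> tuple[list[int], list[int]]:
    """Train/test split keeping the with/without proportion in both parts."""
    rng = np.random.default_rng(seed)
    with_idx = [i for i, r in enumerate(dataset) if r.has_dhrf]
    without_idx = [i for i, r in enumerate(dataset) if not r.has_dhrf]
    rng.shuffle(with_idx)
    rng.shuffle(without_idx)
    n_total = n_train + n_test
    if n_total > len(dataset):
        raise ValueError("n_train + n_test exceeds dataset size")
    take_with = min(int(round(n_total * len(with_idx) / len(dataset))),
                    len(with_idx))
    take_without = min(n_total - take_with, len(without_idx))
    t_with = int(round(n_test / n_total * take_with))
    t_without = n_test - t_with
    test = with_idx[:t_with] + without_idx[:t_without]
    train = (with_idx[t_with:take_with]
             + without_idx[t_without:take_without])[:n_train]
    return train, test


def run_synthetic_experiment(dataset: list[SyntheticRecord],
                             condition: SegmentationCondition,
                             config: ForecasterConfig,
                             split_seed: int = 0,
                             levels: tuple[int, ...] = DEFAULT_LEVELS,
                             n_train: int | None = None,
                             n_test: int | None = None,
                             horizon: int = DEFAULT_HORIZON,
                             wavelet_name: str = "sym4",
                             max_train_windows: int = 8000) -> ExperimentResult:
    """The synthetic validation protocol for one segmentation condition.

    For every requested wavelet level: decompose the final ``modwt_length_s``
    of each record's resting period (J = 8), train one forecaster on the last
    ``lstm_train_length_s`` of the training records' component (pooled, each
    record z-scored by its own training-window stats), forecast ``horizon``
    samples into the task window of each test record, and score against the
    same component of the full-record decomposition, in normalized units.
    """
    fs = dataset[0].fs
    rest_n = dataset[0].rest_samples
    m_n = condition.modwt_samples(fs)
    l_n = condition.lstm_samples(fs)
    if m_n > rest_n:
        raise ValueError("condition MODWT length exceeds the resting period")
    for rec in dataset:
        if rec.combined.n < rest_n + horizon:
            raise ValueError("record too short for the requested horizon")

    if n_test is None:
        n_test = max(1, len(dataset) // 10)
    if n_train is None:
        n_train = len(dataset) - n_test
    train_idx, test_idx = _stratified_split(dataset, n_train, n_test, split_seed)

    bank = make_filter_bank(wavelet_name, DECOMPOSITION_LEVELS)
    t0 = time.time()

    def rest_components(rec: SyntheticRecord) -> MraComponents:
        seg = rec.combined.slice(rest_n - m_n, rest_n)
        return modwt_mra(modwt_transform(seg, bank))

    def full_components(rec: SyntheticRecord) -> MraComponents:
        return modwt_mra(modwt_transform(rec.combined, bank))

    train_comps = [rest_components(dataset[i]) for i in train_idx]
    test_rest = [rest_components(dataset[i]) for i in test_idx]
    test_full = [full_components(dataset[i]) for i in test_idx]
    log.info("condition %d: decomposed %d records in %.1f s",
             condition.id, len(train_idx) + len(test_idx), time.time() - t0)

    rows = []
    predictions: dict[int, np.ndarray] = {}
    references: dict[int, np.ndarray] = {}
    norms: dict[int, list[NormalizationParams]] = {}
    models: dict[int, TrainedForecaster] = {}
    test_records = [dataset[i] for i in test_idx]

    for level in levels:
        t1 = time.time()
        train_series = [_component(c, level)[-l_n:] for c in train_comps]
        cfg = _level_config(config, level, l_n, len(train_idx), max_train_windows)
        model = train_pooled_forecaster(train_series, cfg, wavelet_level=level)
        models[level] = model

        ctxs, refs, lnorms = [], [], []
        for comps, fcomps in zip(test_rest, test_full):
            comp = _component(comps, level)
            # forecasts and errors live in the record's training-window
            # z-units, the same normalization the network was trained under
            norm = NormalizationParams.from_samples(comp[-l_n:])
            ctxs.append(norm.normalize(comp[-cfg.context_samples:]))
            lnorms.append(norm)
            refs.append(norm.normalize(
                _component(fcomps, level)[rest_n:rest_n + horizon]))
        preds = forecast_batch(model, np.asarray(ctxs), horizon)
        predictions[level] = preds
        references[level] = np.asarray(refs)
        norms[level] = lnorms

        for i, rec in enumerate(test_records):
            rows.append({
                "record_id": i, "wavelet_level": level,
                "group": "with_dhrf" if rec.has_dhrf else "without_dhrf",
                "mae": mae(references[level][i], preds[i]),
                "rmse": rmse(references[level][i], preds[i]),
            })
        log.info("condition %d wavelet %d: trained + forecast in %.1f s "
                 "(final loss %.4f)", condition.id, level, time.time() - t1,
                 model.loss_history[-1] if model.loss_history else float("nan"))

    errors = pd.DataFrame(rows)
    groups = errors["group"].nunique()
    metrics = (summarize_groups(errors) if groups == 2
               else errors.groupby("wavelet_level")[["mae", "rmse"]]
               .agg(["mean", "std"]).reset_index())
    return ExperimentResult(condition=condition, levels=tuple(levels),
                            horizon=horizon, errors=errors, metrics=metrics,
                            predictions=predictions, references=references,
                            norms=norms, models=models,
                            test_records=test_records, split_seed=split_seed)


def denoise_task_segment(record: Signal1D, rest_end_index: int,
                         spec: DenoiseSpec,
                         models: dict[int, TrainedForecaster],
                         wavelet_name: str = "sym4") -> Signal1D:
    """Subtract the predicted low-frequency components from the task window.

    The resting portion ``record[:rest_end_index]`` is decomposed (J = 8);
    each requested component is z-scored by its own resting stats, forecast
    ``horizon`` samples with its model, de-normalized, and the summed
    prediction subtracted from the measured task segment.
    """
    horizon = spec.horizon_samples
    if record.n < rest_end_index + horizon:
        raise ValueError("record does not extend a full horizon past rest_end_index")
    missing = [lv for lv in spec.wavelet_levels if lv not in models]
    if missing:
        raise ValueError(f"no trained forecaster for wavelet level(s) {missing}")
    bank = make_filter_bank(wavelet_name, DECOMPOSITION_LEVELS)
    comps = modwt_mra(modwt_transform(record.slice(0, rest_end_index), bank))
    predicted_noise = np.zeros(horizon)
    for level in spec.wavelet_levels:
        comp = _component(comps, level)
        norm = NormalizationParams.from_samples(comp)
        model = models[level]
        pred = forecast_batch(model, norm.normalize(comp)[None, :], horizon)[0]
        predicted_noise += norm.denormalize(pred)
    task = record.samples[rest_end_index:rest_end_index + horizon]
    return Signal1D(task - predicted_noise, record.fs, "denoised_task")


def run_leave_one_out(subjects: list[list[Signal1D]],
                      config: ForecasterConfig,
                      horizons_s: tuple[float, ...] = (1, 3, 5, 10, 15, 30),
                      levels: tuple[int, ...] = DEFAULT_LEVELS,
                      train_seconds: float = 570.0,
                      horizon: int = DEFAULT_HORIZON,
                      wavelet_name: str = "sym4",
                      max_train_windows: int = 8000
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level leave-one-out over multi-channel recordings.

    For each fold, per-wavelet forecasters are trained on all channels of the
    other subjects pooled (first ``train_seconds`` of each channel), then the
    held-out subject's channels are forecast 30 s ahead and scored per
    cumulative window.  Returns (summary, per_channel): the summary holds
    mean/std MAE/RMSE per (wavelet level, window).
    """
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    fs = subjects[0][0].fs
    train_n = seconds_to_samples(train_seconds, fs)
    bank = make_filter_bank(wavelet_name, DECOMPOSITION_LEVELS)

    def comps_of(sig: Signal1D, upto: int | None) -> MraComponents:
        seg = sig if upto is None else sig.slice(0, upto)
        return modwt_mra(modwt_transform(seg, bank))

    rows = []
    for fold, held in enumerate(subjects):
        pool = [ch for s, chans in enumerate(subjects) if s != fold
                for ch in chans]
        pool_comps = [comps_of(ch, train_n) for ch in pool]
        held_train = [comps_of(ch, train_n) for ch in held]
        held_full = [comps_of(ch, None) for ch in held]
        for level in levels:
            cfg = _level_config(config, level, train_n, len(pool),
                                max_train_windows)
            cfg = replace(cfg, seed=cfg.seed + 1009 * fold)
            model = train_pooled_forecaster(
                [_component(c, level) for c in pool_comps], cfg, level)
            ctxs, refs, lnorms = [], [], []
            for tr, fu in zip(held_train, held_full):
                comp = _component(tr, level)
                norm = NormalizationParams.from_samples(comp)
                ctxs.append(norm.normalize(comp[-cfg.context_samples:]))
                lnorms.append(norm)
                refs.append(norm.normalize(
                    _component(fu, level)[train_n:train_n + horizon]))
            preds = forecast_batch(model, np.asarray(ctxs), horizon)
            for c, (ref, pred) in enumerate(zip(refs, preds)):
                wdf = windowed_errors(ref, pred, fs, horizons_s)
                for _, r in wdf.iterrows():
                    rows.append({"subject": fold, "channel": c,
                                 "wavelet_level": level,
                                 "window_s": r["window_s"],
                                 "mae": r["mae"], "rmse": r["rmse"]})
    per_channel = pd.DataFrame(rows)
    summary = (per_channel.groupby(["wavelet_level", "window_s"])[["mae", "rmse"]]
               .agg(["mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index(), per_channel
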