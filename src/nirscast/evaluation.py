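"""Forecast-error metrics, group comparison, and windowed error analysis.

MAE = mean |y_i - yhat_i|, RMSE = sqrt(mean (y_i - yhat_i)^2); the with- and
without-response groups are compared with a two-sample Welch t-test, flagged
at p < 0.05 (*) and p < 0.01 (**).  Windowed errors are cumulative from the
task onset: the w-second window scores the first round(w * fs) samples of the
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signal import seconds_to_samples

__all__ = [
    "mae",
    "rmse",
    "GroupComparison",
    "compare_groups",
    "significance_marker",
    "windowed_errors",
    "summarize_groups",
]


def _check(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return y, yhat


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error."""
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error; >= MAE for any pair."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    degenerate: bool = False

    @property
    def marker(self) -> str:
        return significance_marker(self.p_value)


def significance_marker(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(values_a: np.ndarray, values_b: np.ndarray) -> GroupComparison:
    """Welch two-sample t-test (unequal variances).

    Two identical zero-variance groups are degenerate: by convention p = 1,
    statistic 0, with the result flagged.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, degenerate=True)
        return GroupComparison(np.inf if a.mean() > b.mean() else -np.inf,
                               0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(float(res.statistic), float(res.pvalue))


def windowed_errors(y: np.ndarray, yhat: np.ndarray, fs: float,
                    windows_s: tuple[float, ...] = (1, 3, 5, 10, 15, 30)
                    ) -> pd.DataFrame:
    """Cumulative-from-onset MAE/RMSE over the first round(w * fs) samples."""
    y, yhat = _check(y, yhat)
    rows = []
    for w in windows_s:
        k = seconds_to_samples(w, fs)
        if k > y.size:
            raise ValueError(f"window {w} s ({k} samples) exceeds horizon {y.size}")
        rows.append({"window_s": float(w), "n_samples": k,
                     "mae": mae(y[:k], yhat[:k]), "rmse": rmse(y[:k], yhat[:k])})
    return pd.DataFrame(rows)


def summarize_groups(df: pd.DataFrame,
                     group_col: str = "group",
                     value_cols: tuple[str, ...] = ("mae", "rmse"),
                     by: tuple[str, ...] = ("wavelet_level",)) -> pd.DataFrame:
    """Long-format per-record errors -> per-group mean/std + Welch p per cell.

    ``df`` holds one row per (record, *by) with columns ``group`` in
    {"with_dhrf", "without_dhrf"} and the value columns.  The output has one
    row per *by combination with mean/std per group and p-values, mirroring
    the per-wavelet summary tables.
    """
    rows = []
    for keys, sub in df.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        groups = {g: s for g, s in sub.groupby(group_col)}
        for col in value_cols:
            for gname, s in groups.items():
                row[f"{col}_mean_{gname}"] = float(s[col].mean())
                row[f"{col}_std_{gname}"] = float(s[col].std(ddof=1))
                row[f"n_{gname}"] = int(len(s))
            if len(groups) == 2:
                a = groups["with_dhrf"][col].to_numpy()
                b = groups["without_dhrf"][col].to_numpy()
                if min(a.size, b.size) >= 2:
                    cmp = compare_groups(a, b)
                    row[f"p_value_{col}"] = cmp.p_value
                    row[f"sig_{col}"] = cmp.marker
                else:        # a single record per group: no test possible
                    row[f"p_value_{col}"] = float("nan")
                    row[f"sig_{col}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
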