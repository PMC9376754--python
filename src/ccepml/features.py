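"""Per-test descriptive features of a preprocessed CCEP.

Each stimulation test yields one row: channel-amplitude summaries (max /
mean / min oscillation amplitude over present channels), the mean of the
selected trace, up to two local maxima and two local minima with their
latencies (peaks at least 20 ms apart and at least 5 μV from the trace
mean, the convention neurophysiologists use to read N1/N2-type deflections),
and optionally the p-value of an augmented Dickey–Fuller stationarity test.
Missing extrema are restituted either with zeros or with training-set ratio
means; all model inputs are min–max normalized with statistics learned on
training rows only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.tsa.stattools import adfuller

from .io_edf import LabelledTest
from .preprocess import PreprocessParams, SmoothedSignal, preprocess_channels, select_channel

__all__ = [
    "FeatureParams",
    "NormalizationStats",
    "ImputeStats",
    "DegenerateSignalError",
    "FEATURE_COLUMNS",
    "MODEL_INPUT_COLUMNS",
    "EXTREMUM_COLUMNS",
    "amplitude_summaries",
    "detect_extrema",
    "adf_pvalue",
    "fit_impute_stats",
    "impute_missing",
    "fit_normalizer",
    "apply_normalizer",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

#: FeatureTable column order (CSV contract); adf_pvalue appended when computed
FEATURE_COLUMNS = [
    "test_id",
    "patient_id",
    "target",
    "max_amp",
    "mean_amp",
    "min_amp",
    "signal_mean",
    "peak1_value",
    "peak1_latency",
    "peak2_value",
    "peak2_latency",
    "trough1_value",
    "trough1_latency",
    "trough2_value",
    "trough2_latency",
]

#: numeric columns fed to the classifiers (ADF excluded by default)
MODEL_INPUT_COLUMNS = FEATURE_COLUMNS[3:]

EXTREMUM_COLUMNS = FEATURE_COLUMNS[7:]


class DegenerateSignalError(ValueError):
    """Raised when a statistic is undefined on a constant trace."""


@dataclass(frozen=True)
class FeatureParams:
    """Extremum-detection and feature-assembly settings.

    ``peak_min_height`` is measured relative to the valid-range mean of the
    smoothed trace; maxima must rise at least that far above it, minima fall
    at least that far below.
    """

    peak_min_distance: int = 20      # ms between retained peaks
    peak_min_height: float = 5.0     # μV from the trace mean
    max_maxima: int = 2
    max_minima: int = 2
    impute_scheme: Literal["zeros", "ratio_mean"] = "zeros"
    include_adf: bool = False

    def __post_init__(self) -> None:
        if self.peak_min_distance < 1:
            raise ValueError("peak_min_distance must be >= 1 ms")
        if self.peak_min_height <= 0:
            raise ValueError("peak_min_height must be positive")


def amplitude_summaries(per_channel: Sequence[SmoothedSignal]
                        ) -> tuple[float, float, float]:
    """(max, mean, min) of per-channel oscillation amplitudes."""
    if not per_channel:
        raise ValueError("no present channels")
    amps = np.array([s.amplitude for s in per_channel])
    return float(amps.max()), float(amps.mean()), float(amps.min())


def detect_extrema(signal: SmoothedSignal,
                   params: FeatureParams = FeatureParams()
                   ) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Constrained local extrema of the smoothed trace.

    Maxima are local peaks at least ``peak_min_height`` μV above the
    valid-range mean and pairwise at least ``peak_min_distance`` ms apart
    (higher peaks win the distance conflict); minima are found on the
    negated trace symmetrically. The ``max_maxima``/``max_minima`` largest
    are kept, then reported in latency order as ``(latency_ms, value_uV)``.
    """
    x = signal.values
    mean = x.mean()

    def _side(y: np.ndarray, height: float, keep: int) -> list[tuple[int, float]]:
        idx, _ = find_peaks(y, height=height,
                            distance=params.peak_min_distance)
        if idx.size == 0:
            return []
        top = idx[np.argsort(y[idx], kind="stable")[::-1][:keep]]
        top = np.sort(top)
        return [(int(signal.start_index + i), float(x[i])) for i in top]

    maxima = _side(x, mean + params.peak_min_height, params.max_maxima)
    minima = _side(-x, -(mean - params.peak_min_height), params.max_minima)
    return maxima, minima


def adf_pvalue(signal: SmoothedSignal) -> float:
    """p-value of the augmented Dickey–Fuller unit-root test on the trace.

    Small p-values indicate a stationary series; CCEP traces are typically
    non-stationary over the 300 ms window, which is why this feature is
    excluded from the default model inputs.
    """
    x = signal.values
    if x.size < 30:
        raise ValueError(f"trace of length {x.size} too short for the ADF test")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("ADF test undefined on a constant trace")
    return float(adfuller(x)[1])


def build_feature_table(tests: Iterable[LabelledTest],
                        feature_params: FeatureParams = FeatureParams(),
                        preprocess_params: PreprocessParams = PreprocessParams(),
                        ) -> pd.DataFrame:
    """One feature row per labelled test (missing extrema left as NaN).

    Imputation and normalization are *not* applied here — they carry
    training-set statistics and belong inside each resampling repetition.
    """
    rows = []
    for t in tests:
        per_channel = preprocess_channels(t.epoch, preprocess_params)
        selected = select_channel(per_channel)
        max_amp, mean_amp, min_amp = amplitude_summaries(per_channel)
        maxima, minima = detect_extrema(selected, feature_params)
        row = {
            "test_id": t.test_id,
            "patient_id": t.patient_id,
            "target": int(t.target),
            "max_amp": max_amp,
            "mean_amp": mean_amp,
            "min_amp": min_amp,
            "signal_mean": float(selected.values.mean()),
        }
        for k in range(2):
            lat, val = maxima[k] if k < len(maxima) else (np.nan, np.nan)
            row[f"peak{k + 1}_latency"], row[f"peak{k + 1}_value"] = lat, val
            lat, val = minima[k] if k < len(minima) else (np.nan, np.nan)
            row[f"trough{k + 1}_latency"], row[f"trough{k + 1}_value"] = lat, val
        if feature_params.include_adf:
            row["adf_pvalue"] = adf_pvalue(selected)
        rows.append(row)
    cols = FEATURE_COLUMNS + (["adf_pvalue"] if feature_params.include_adf else [])
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputeStats:
    """Training-set statistics backing ratio-mean restitution.

    Ratios are means over training rows that have the extremum:
    first peak relative to the trace amplitude, second peak relative to the
    first; troughs use magnitudes with the sign of the training-mean trough.
    Latencies are imputed with the training-mean latency of the extremum.
    """

    ratios: dict[str, float] = field(default_factory=dict)
    signs: dict[str, float] = field(default_factory=dict)
    latency_means: dict[str, float] = field(default_factory=dict)


def fit_impute_stats(train: pd.DataFrame) -> ImputeStats:
    """Learn ratio-mean restitution statistics from training rows only."""
    st = ImputeStats()

    def ratio(num: pd.Series, den: pd.Series) -> float:
        ok = num.notna() & den.notna() & (den.abs() > 1e-12)
        return float((num[ok] / den[ok]).mean()) if ok.any() else math.nan

    st.ratios["peak1_value"] = ratio(train["peak1_value"], train["max_amp"])
    st.ratios["peak2_value"] = ratio(train["peak2_value"], train["peak1_value"])
    st.ratios["trough1_value"] = ratio(train["trough1_value"].abs(), train["max_amp"])
    st.ratios["trough2_value"] = ratio(train["trough2_value"].abs(),
                                       train["trough1_value"].abs())
    for col in ("trough1_value", "trough2_value"):
        m = train[col].mean()
        st.signs[col] = float(np.sign(m)) if pd.notna(m) and m != 0 else 1.0
    for col in ("peak1_latency", "peak2_latency", "trough1_latency",
                "trough2_latency"):
        st.latency_means[col] = float(train[col].mean())
    return st


def impute_missing(table: pd.DataFrame, scheme: str = "zeros",
                   stats: ImputeStats | None = None) -> pd.DataFrame:
    """Fill missing extremum values/latencies; never touches observed cells.

    ``zeros``: every missing cell becomes 0. ``ratio_mean``: the first peak
    is restituted as (training mean of peak1/amplitude) × the row's
    amplitude, the second as (training mean of peak2/peak1) × the row's
    first peak (after its own restitution); troughs analogously on
    magnitudes; latencies take the training-mean latency. An extremum never
    observed in training falls back to zeros with a warning.
    """
    out = table.copy()
    ext_cols = [c for c in EXTREMUM_COLUMNS if c in out.columns]
    if scheme == "zeros":
        out[ext_cols] = out[ext_cols].fillna(0.0)
        return out
    if scheme != "ratio_mean":
        raise ValueError(f"unknown imputation scheme {scheme!r}")
    if stats is None:
        raise ValueError("ratio_mean imputation requires training ImputeStats")

    def fill_value(col: str, base: pd.Series, *, magnitude: bool) -> None:
        r = stats.ratios[col]
        miss = out[col].isna()
        if not miss.any():
            return
        if math.isnan(r) or base[miss].isna().any():
            logger.warning("no training rows support ratio imputation of %s; "
                           "falling back to zeros", col)
            out.loc[miss, col] = 0.0
            return
        if magnitude:  # trough ratios are on |value|; restore the train sign
            out.loc[miss, col] = stats.signs[col] * r * base[miss].abs()
        else:
            out.loc[miss, col] = r * base[miss]

    fill_value("peak1_value", out["max_amp"], magnitude=False)
    fill_value("peak2_value", out["peak1_value"], magnitude=False)
    fill_value("trough1_value", out["max_amp"], magnitude=True)
    fill_value("trough2_value", out["trough1_value"], magnitude=True)
    for col, m in stats.latency_means.items():
        miss = out[col].isna()
        if miss.any():
            if math.isnan(m):
                logger.warning("no training latencies for %s; using 0", col)
                m = 0.0
            out.loc[miss, col] = m
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationStats:
    """Per-feature (min, max) learned from a training table."""

    mins: pd.Series
    maxs: pd.Series


def fit_normalizer(train: pd.DataFrame,
                   columns: Sequence[str] | None = None) -> NormalizationStats:
    """Min–max statistics from training rows only."""
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty table")
    cols = list(columns) if columns is not None else [
        c for c in train.columns if c in MODEL_INPUT_COLUMNS or c == "adf_pvalue"
    ]
    sub = train[cols].astype(float)
    return NormalizationStats(mins=sub.min(), maxs=sub.max())


def apply_normalizer(table: pd.DataFrame, stats: NormalizationStats
                     ) -> pd.DataFrame:
    """Map each feature to (x − min)/(max − min) using training statistics.

    A feature constant in training maps to 0 everywhere; out-of-sample
    values may legitimately fall outside [0, 1].
    """
    out = table.copy()
    span = stats.maxs - stats.mins
    for col in stats.mins.index:
        if span[col] == 0:
            out[col] = 0.0
        else:
            out[col] = (out[col].astype(float) - stats.mins[col]) / span[col]
    return out
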