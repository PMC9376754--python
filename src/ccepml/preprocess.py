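"""Waveform reduction for a single CCEP epoch.

The raw 7500-sample, 300 ms trace is reduced to one value per millisecond
(bin averaging over 25-sample blocks), smoothed with a trailing 20 ms moving
average, trimmed at its start to discard the stimulus artifact, and finally
the channel with the largest post-trim oscillation amplitude is selected for
feature extraction — the remaining channels typically carry only
low-amplitude impulse noise.

Index convention: one bin is one millisecond. The moving average is
*trailing* — the first 20 bins produce the smoothed value at index 20 — so
smoothed indices run from ``ma_window`` to ``n_bins`` inclusive, and latency
features inherit the resulting ~``ma_window/2`` ms lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_edf import EcogEpoch

__all__ = [
    "PreprocessParams",
    "SmoothedSignal",
    "bin_average",
    "moving_average",
    "trim_artifact",
    "select_channel",
    "preprocess_channels",
    "preprocess_epoch",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the reduction, in bins (= milliseconds).

    Parameters
    ----------
    n_bins, bin_size
        300 one-millisecond bins of 25 raw samples each.
    ma_window
        Trailing moving-average window (20 ms).
    artifact_factor
        A candidate start value is an artifact when its deviation from the
        mean of the remaining signal exceeds ``artifact_factor`` times the
        remaining signal's half peak-to-peak amplitude.
    max_extra_shift
        Cap on artifact-driven shifts beyond the mandatory one (10 ms).
    mandatory_shift
        The start index always advances by this much (1 ms) to discard the
        first millisecond, artifact or not.
    """

    n_bins: int = 300
    bin_size: int = 25
    ma_window: int = 20
    artifact_factor: float = 1.25
    max_extra_shift: int = 10
    mandatory_shift: int = 1

    def __post_init__(self) -> None:
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.artifact_factor <= 1:
            raise ValueError("artifact_factor must exceed 1")
        if self.max_extra_shift < 0:
            raise ValueError("max_extra_shift must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_bins * self.bin_size


@dataclass
class SmoothedSignal:
    """A binned, smoothed, artifact-trimmed single-channel trace.

    ``values[k]`` is the smoothed signal at millisecond ``start_index + k``;
    ``amplitude`` is max − min over the valid (post-trim) range.
    """

    values: np.ndarray
    start_index: int
    channel_index: int = 0
    amplitude: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("empty smoothed signal")
        self.amplitude = float(self.values.max() - self.values.min())

    @property
    def latencies(self) -> np.ndarray:
        """Absolute millisecond index of each value."""
        return self.start_index + np.arange(self.values.size)


def bin_average(raw: np.ndarray, params: PreprocessParams = PreprocessParams()
                ) -> np.ndarray:
    """Average consecutive ``bin_size`` samples: 7500 values -> 300 means."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size != params.n_samples:
        raise ValueError(
            f"expected a vector of {params.n_samples} samples "
            f"({params.n_bins} bins × {params.bin_size}), got length {raw.size}"
        )
    return raw.reshape(params.n_bins, params.bin_size).mean(axis=1)


def moving_average(binned: np.ndarray,
                   params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Trailing moving average: output[j] = mean of the preceding window.

    Returns ``len(binned) − ma_window + 1`` values; element ``j`` is the
    smoothed signal at bin index ``ma_window + j``, i.e. the mean of bins
    ``[j, j + ma_window)``.
    """
    binned = np.asarray(binned, dtype=float)
    w = params.ma_window
    if binned.size < w:
        raise ValueError(f"input length {binned.size} < ma_window {w}")
    c = np.concatenate([[0.0], np.cumsum(binned)])
    return (c[w:] - c[:-w]) / w


def trim_artifact(smoothed: np.ndarray,
                  params: PreprocessParams = PreprocessParams()
                  ) -> tuple[int, np.ndarray]:
    """Shift the start index past any residual stimulus artifact.

    The start always advances by ``mandatory_shift`` bins. Then, up to
    ``max_extra_shift`` times: the candidate start value is compared with
    the rest of the signal — if its deviation from the rest's mean exceeds
    ``artifact_factor`` × (half the rest's peak-to-peak amplitude), the
    start advances one more bin.

    Returns ``(start_offset, trimmed)`` where ``start_offset`` counts bins
    removed from the front of ``smoothed`` (add the first smoothed index,
    ``ma_window``, for the absolute start in ms).
    """
    smoothed = np.asarray(smoothed, dtype=float)
    s = params.mandatory_shift
    if smoothed.size < s + 2:
        raise ValueError(
            f"smoothed signal of length {smoothed.size} too short to trim "
            f"(mandatory shift {s})"
        )
    for _ in range(params.max_extra_shift):
        rest = smoothed[s + 1:]
        if rest.size < 2:
            break
        half_range = (rest.max() - rest.min()) / 2.0
        if abs(smoothed[s] - rest.mean()) > params.artifact_factor * half_range:
            s += 1
        else:
            break
    return s, smoothed[s:]


def select_channel(per_channel: list[SmoothedSignal]) -> SmoothedSignal:
    """The trace with the highest oscillation amplitude; ties -> lowest index."""
    if not per_channel:
        raise ValueError("no present channels to select from")
    return max(per_channel, key=lambda s: (s.amplitude, -s.channel_index))


def preprocess_channels(epoch: EcogEpoch,
                        params: PreprocessParams = PreprocessParams()
                        ) -> list[SmoothedSignal]:
    """Bin, smooth and trim every present channel of an epoch."""
    out = []
    for ch in range(epoch.n_channels):
        if not epoch.present[ch]:
            continue
        binned = bin_average(epoch.samples[ch], params)
        smoothed = moving_average(binned, params)
        offset, trimmed = trim_artifact(smoothed, params)
        out.append(SmoothedSignal(values=trimmed,
                                  start_index=params.ma_window + offset,
                                  channel_index=ch))
    if not out:
        raise ValueError(f"epoch {epoch.test_id!r} has no present channels")
    return out


def preprocess_epoch(epoch: EcogEpoch,
                     params: PreprocessParams = PreprocessParams()
                     ) -> SmoothedSignal:
    """Full reduction of one epoch to its highest-amplitude smoothed trace."""
    return select_channel(preprocess_channels(epoch, params))
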