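"""Debug views of preprocessed traces (per-channel smoothed signals)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .preprocess import SmoothedSignal

__all__ = ["smoothed_to_frame", "dump_smoothed_csv", "plot_smoothed"]


def smoothed_to_frame(per_channel: Sequence[SmoothedSignal]) -> pd.DataFrame:
    """Long-format table of smoothed traces: channel, latency_ms, value_uv."""
    frames = [
        pd.DataFrame({"channel": s.channel_index,
                      "start_index": s.start_index,
                      "latency_ms": s.latencies,
                      "value_uv": s.values})
        for s in per_channel
    ]
    return pd.concat(frames, ignore_index=True)


def dump_smoothed_csv(per_channel: Sequence[SmoothedSignal],
                      path: str | Path) -> None:
    smoothed_to_frame(per_channel).to_csv(path, index=False)


def plot_smoothed(signal: SmoothedSignal, ax=None,
                  extrema: tuple[list, list] | None = None):
    """Averaged-and-smoothed trace with start index and optional extrema.

    Maxima are drawn as green crosses, minima as red, matching how
    neurophysiologists annotate evoked-potential readouts.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(signal.latencies, signal.values, lw=1.2,
            label=f"channel {signal.channel_index}")
    ax.axvline(signal.start_index, color="grey", ls="--", lw=0.8,
               label=f"start = {signal.start_index} ms")
    if extrema is not None:
        maxima, minima = extrema
        if maxima:
            ax.scatter(*zip(*maxima), marker="x", color="green", zorder=3)
        if minima:
            ax.scatter(*zip(*minima), marker="x", color="red", zorder=3)
    ax.set_xlabel("time, ms")
    ax.set_ylabel("amplitude, μV")
    ax.legend(loc="best", fontsize=8)
    return ax
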