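"""Beam-on interval plots (matplotlib).

Renders a breathing curve with its beam-on periods shaded, the style
used to compare a continuous spiral beam with the discontinuous
per-couch-position intervals of a breathing-adapted sequence scan.  The
displayed period is restricted to 90 s by default for comparability.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default
import matplotlib.pyplot as plt
import numpy as np

from .signal_io import BeamOnIntervals, BreathingSignal


def plot_beam_on(
    signal: BreathingSignal,
    intervals: BeamOnIntervals,
    window_s: float = 90.0,
    ax: "plt.Axes | None" = None,
    title: str | None = None,
) -> "plt.Axes":
    """Plot a breathing curve with shaded beam-on intervals.

    Only the first ``window_s`` seconds (from the first beam-on start,
    or the trace start if the beam never fires) are shown.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    t0 = intervals.intervals[0][0] if len(intervals) else float(signal.times[0])
    t1 = t0 + window_s
    mask = (signal.times >= t0) & (signal.times <= t1)
    ax.plot(signal.times[mask], signal.amplitudes[mask], lw=0.8, color="k")
    for start, end in intervals.intervals:
        if end < t0 or start > t1:
            continue
        ax.axvspan(max(start, t0), min(end, t1), color="tab:blue", alpha=0.25, lw=0)
    ax.set_xlim(t0, t1)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("amplitude [a.u.]")
    if title:
        ax.set_title(title)
    return ax
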