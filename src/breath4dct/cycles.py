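"""End-inhalation peak detection, cycle segmentation, phase binning.

A breathing cycle runs from one end-inhalation peak to the next
(half-open in time).  "Inhalation points" are taken to be end-inhalation
maxima, consistent with the convention that larger amplitude means more
inhaled.  The per-cycle peak-to-peak amplitude is max - min of the
samples inside the cycle interval.  The patient's average breathing
cycle is estimated by the *median* inter-peak duration: the arithmetic
mean is inflated by the very pauses the 1.5x pause rule must detect,
which would make the rule self-defeating, whereas the median is
pause-robust.

Phase binning is time-fraction (phase-based): a sample at time t inside
cycle [p_i, p_{i+1}) gets phase fraction f = (t - p_i)/(p_{i+1} - p_i)
and bin floor(f * n_phases), the scheme used for retrospective 10-phase
4D CT reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientCyclesError, ValidationError
from .preprocessing import PreprocessedSignal
from .signal_io import BreathingSignal

UNASSIGNED = -1  # phase-bin value for samples outside any cycle


@dataclass
class CycleSegmentation:
    """Cycle structure of one breathing curve."""

    peak_times_s: np.ndarray
    cycle_intervals: list[tuple[float, float]]
    cycle_p2p_amplitudes: np.ndarray
    inter_peak_durations_s: np.ndarray
    mean_cycle_s: float  # median inter-peak duration (pause-robust)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_intervals)


@dataclass
class PhaseAssignment:
    """Per-sample phase-bin index (UNASSIGNED outside any cycle).

    ``fractions`` carries the continuous phase fraction f in [0, 1)
    per sample (nan outside any cycle); ``bins`` is floor(f * n_phases).
    """

    bins: np.ndarray
    n_phases: int
    fractions: np.ndarray | None = None


def detect_inhalation_peaks(
    signal: BreathingSignal,
    min_prominence: float = 0.2,
    min_separation_s: float = 1.0,
) -> np.ndarray:
    """Detect end-inhalation peaks.

    Local maxima with topographic prominence >= ``min_prominence`` (a
    fraction of the unit range for normalized signals), thinned so that
    surviving peaks are >= ``min_separation_s`` apart.  On a conflict
    the higher peak wins; on equal height the earlier one.  The defaults
    (0.2 of unit range, 1.0 s) reject cardiac/noise ripple while
    admitting breathing rates up to ~30 breaths/min and beyond.

    Raises :class:`InsufficientCyclesError` when fewer than two peaks
    survive (the curve is unanalyzable).
    """
    if not 0 < min_prominence < 1:
        raise ValidationError("min_prominence must lie in (0, 1)")
    if min_separation_s <= 0:
        raise ValidationError("min_separation_s must be positive")
    x = signal.amplitudes
    idx, _ = find_peaks(x, prominence=min_prominence)
    # explicit thinning: process by descending height, earlier on ties
    order = sorted(range(len(idx)), key=lambda k: (-x[idx[k]], idx[k]))
    kept: list[int] = []
    times = signal.times
    for k in order:
        t = times[idx[k]]
        if all(abs(t - times[idx[j]]) >= min_separation_s for j in kept):
            kept.append(k)
    peaks = np.sort(idx[kept])
    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"only {len(peaks)} peak(s) found; need at least 2"
        )
    return times[peaks]


def segment_cycles(
    signal: BreathingSignal, peak_times: np.ndarray
) -> CycleSegmentation:
    """Segment a curve into half-open peak-to-peak cycles.

    The per-cycle peak-to-peak amplitude is max - min of the samples in
    each interval.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if len(peak_times) < 2:
        raise InsufficientCyclesError("need at least 2 peaks to segment cycles")
    t = signal.times
    x = signal.amplitudes
    left = np.searchsorted(t, peak_times[:-1], side="left")
    right = np.searchsorted(t, peak_times[1:], side="left")  # half-open
    p2p = np.array(
        [float(np.max(x[i:j]) - np.min(x[i:j])) for i, j in zip(left, right)]
    )
    gaps = np.diff(peak_times)
    return CycleSegmentation(
        peak_times_s=peak_times,
        cycle_intervals=[
            (float(a), float(b)) for a, b in zip(peak_times[:-1], peak_times[1:])
        ],
        cycle_p2p_amplitudes=p2p,
        inter_peak_durations_s=gaps,
        mean_cycle_s=float(np.median(gaps)),
    )


def assign_phase(
    signal: BreathingSignal, seg: CycleSegmentation, n_phases: int = 10
) -> PhaseAssignment:
    """Assign each sample a breathing-phase bin in 0..n_phases-1.

    Samples before the first or at/after the last peak are UNASSIGNED.
    """
    if n_phases < 2:
        raise ValidationError("n_phases must be >= 2")
    t = signal.times
    peaks = seg.peak_times_s
    bins = np.full(len(t), UNASSIGNED, dtype=int)
    fractions = np.full(len(t), np.nan)
    # cycle index per sample: peaks[c] <= t < peaks[c+1]
    c = np.searchsorted(peaks, t, side="right") - 1
    inside = (c >= 0) & (c < len(peaks) - 1)
    ci = c[inside]
    f = (t[inside] - peaks[ci]) / (peaks[ci + 1] - peaks[ci])
    fractions[inside] = f
    bins[inside] = np.minimum((f * n_phases).astype(int), n_phases - 1)
    return PhaseAssignment(bins=bins, n_phases=n_phases, fractions=fractions)
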