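"""Scan-window restriction, linear drift correction, normalization.

All irregularity statistics are computed on the respiratory signal
restricted to scan time (first to last beam-on sample), after removing a
linear baseline drift and rescaling the excursion to the unit range.
The fixed order window -> drift-correct -> normalize makes every
downstream amplitude statistic a dimensionless fraction of the total
respiratory excursion during the scan, comparable across patients and
cohorts, and invariant under positive affine transforms of the raw
trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, EmptyWindowError, ZeroRangeError
from .signal_io import BreathingSignal


@dataclass
class Provenance:
    """Record of the preprocessing applied to a trace."""

    window_s: tuple[float, float] | None = None
    drift_slope_removed: float | None = None  # a.u./s
    scale: float | None = None   # raw amplitude units per normalized unit
    offset: float | None = None  # raw amplitude mapped to 0


@dataclass
class PreprocessedSignal(BreathingSignal):
    """A breathing signal after windowing, drift removal and min-max
    normalization, with full provenance.  Amplitudes lie in [0, 1]."""

    provenance: Provenance | None = None


def window_to_beam_on(signal: BreathingSignal) -> BreathingSignal:
    """Restrict a signal to [first beam-on sample, last beam-on sample].

    Both endpoints are inclusive.  Raises :class:`EmptyWindowError` when
    no sample is flagged beam-on.
    """
    if signal.beam_on is None or not signal.beam_on.any():
        raise EmptyWindowError("no beam-on sample in signal")
    on = np.flatnonzero(signal.beam_on)
    i, j = int(on[0]), int(on[-1])
    return BreathingSignal(
        times=signal.times[i : j + 1].copy(),
        amplitudes=signal.amplitudes[i : j + 1].copy(),
        beam_on=signal.beam_on[i : j + 1].copy(),
        curve_id=signal.curve_id,
    )


def remove_linear_drift(signal: BreathingSignal) -> tuple[BreathingSignal, float]:
    """Subtract the OLS line fit of amplitude vs. time.

    Returns the corrected signal and the removed slope (a.u./s).  The
    mean level is preserved (only the slope term is removed), so the
    correction is a pure de-tilting.
    """
    t = signal.times
    if np.ptp(t) == 0:
        raise DegenerateFitError("constant time vector")
    slope, intercept = np.polyfit(t, signal.amplitudes, 1)
    corrected = signal.amplitudes - slope * (t - np.mean(t))
    return (
        BreathingSignal(
            times=t.copy(),
            amplitudes=corrected,
            beam_on=None if signal.beam_on is None else signal.beam_on.copy(),
            curve_id=signal.curve_id,
        ),
        float(slope),
    )


def normalize(
    signal: BreathingSignal, provenance: Provenance | None = None
) -> PreprocessedSignal:
    """Affinely rescale so min amplitude = 0 and max = 1.

    Raises :class:`ZeroRangeError` on a constant signal.  The recorded
    provenance scale/offset allow mapping statistics back to raw units.
    """
    amp = signal.amplitudes
    lo, hi = float(np.min(amp)), float(np.max(amp))
    if hi - lo == 0:
        raise ZeroRangeError("constant signal cannot be normalized")
    prov = provenance if provenance is not None else Provenance()
    prov.scale = hi - lo
    prov.offset = lo
    return PreprocessedSignal(
        times=signal.times.copy(),
        amplitudes=(amp - lo) / (hi - lo),
        beam_on=None if signal.beam_on is None else signal.beam_on.copy(),
        curve_id=signal.curve_id,
        provenance=prov,
    )


def preprocess(signal: BreathingSignal) -> PreprocessedSignal:
    """Full pipeline: beam-on window (if flags exist) -> drift removal
    -> min-max normalization."""
    prov = Provenance()
    if signal.beam_on is not None and signal.beam_on.any():
        signal = window_to_beam_on(signal)
        prov.window_s = (float(signal.times[0]), float(signal.times[-1]))
    signal, slope = remove_linear_drift(signal)
    prov.drift_slope_removed = slope
    return normalize(signal, prov)
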