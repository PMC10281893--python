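"""Breathing-curve containers and delimited-text I/O.

A breathing curve is a uniformly sampled respiratory amplitude trace, as
exported by camera-based respiratory gating systems (RPM/RGSC class
devices).  Larger amplitude means more inhaled air, so end-inspiration is
a local maximum.  Vendor export formats are proprietary; this module
defines a neutral delimited-text dialect (columns ``time_s, amplitude,
beam_on``) plus a configurable column map so exported files can be read
after trivial conversion.

Beam-on periods -- the intervals during which the scanner acquired
projection data -- are represented as sorted, non-overlapping half-open
``[start, end)`` intervals in seconds.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MalformedInputError, MissingChannelError

#: Relative tolerance on sample spacing uniformity.
SPACING_RTOL = 1e-6


@dataclass
class BreathingSignal:
    """Uniformly sampled respiratory amplitude trace.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing, uniformly spaced
        within a relative tolerance of 1e-6.
    amplitudes : ndarray
        Respiratory amplitude per sample, arbitrary units; larger value
        means more inhaled.
    beam_on : ndarray of bool, optional
        Per-sample flag marking samples acquired with the beam on.
    curve_id : str
        Identifier used in cohort bookkeeping.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    beam_on: np.ndarray | None = None
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.beam_on is not None:
            self.beam_on = np.asarray(self.beam_on, dtype=bool)
        if self.times.ndim != 1 or self.amplitudes.ndim != 1:
            raise MalformedInputError("times and amplitudes must be 1-D")
        if len(self.times) != len(self.amplitudes):
            raise MalformedInputError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.amplitudes)} amplitudes"
            )
        if self.beam_on is not None and len(self.beam_on) != len(self.times):
            raise MalformedInputError("beam_on length differs from times")
        if len(self.times) < 2:
            raise MalformedInputError("a breathing signal needs at least 2 samples")
        if not np.all(np.isfinite(self.times)):
            raise MalformedInputError("non-finite sample times")
        if not np.all(np.isfinite(self.amplitudes)):
            raise MalformedInputError("non-finite amplitudes")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise MalformedInputError("times must be strictly increasing")
        dt = float(np.median(diffs))
        if np.max(np.abs(diffs - dt)) > SPACING_RTOL * dt:
            raise MalformedInputError(
                "non-uniform sampling: spacing deviates beyond tolerance"
            )
        self._dt = dt

    @property
    def sample_period(self) -> float:
        """Sample period in seconds (median spacing)."""
        return self._dt

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self._dt

    @property
    def duration(self) -> float:
        """Time from first to last sample, in seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class BeamOnIntervals:
    """Sorted, non-overlapping half-open beam-on intervals in seconds."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [(float(a), float(b)) for a, b in self.intervals]
        prev_end = -np.inf
        for start, end in self.intervals:
            if not start < end:
                raise MalformedInputError(f"empty/inverted interval [{start}, {end})")
            if start < prev_end:
                raise MalformedInputError("intervals overlap or are unsorted")
            prev_end = end

    def total_duration(self) -> float:
        return float(sum(end - start for start, end in self.intervals))

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean membership of times ``t`` in any interval (vectorized)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for start, end in self.intervals:
            out |= (t >= start) & (t < end)
        return out

    def to_json(self) -> str:
        return json.dumps([[s, e] for s, e in self.intervals])

    @classmethod
    def from_json(cls, text: str) -> "BeamOnIntervals":
        return cls([(s, e) for s, e in json.loads(text)])

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class Dialect:
    """Column mapping for delimited breathing-curve files.

    ``header=None`` auto-detects a header line (non-numeric first row).
    Columns may be named (requires a header) or integer positions.
    """

    delimiter: str = ","
    time_col: str | int = "time_s"
    amplitude_col: str | int = "amplitude"
    beam_on_col: str | int | None = "beam_on"
    header: bool | None = None


DEFAULT_DIALECT = Dialect()


def _sniff_header(path: Path, delimiter: str) -> bool:
    with open(path, "r") as fh:
        first = fh.readline()
    for token in first.strip().split(delimiter):
        try:
            float(token)
        except ValueError:
            return True
    return False


def _pick_column(df: pd.DataFrame, col: str | int, what: str) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise FormatError(f"missing required {what} column (index {col})")
        return df.iloc[:, col]
    if col not in df.columns:
        raise FormatError(f"missing required {what} column {col!r}")
    return df[col]


def read_breathing_curve(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    curve_id: str | None = None,
) -> BreathingSignal:
    """Read a delimited-text breathing curve.

    The sample rate is inferred from the median time spacing.  Raises
    :class:`FormatError` for missing columns and
    :class:`MalformedInputError` for non-uniform sampling.
    """
    path = Path(path)
    header = dialect.header
    if header is None:
        header = _sniff_header(path, dialect.delimiter)
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if header else None,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not header:
        # positional access only
        time_col = dialect.time_col if isinstance(dialect.time_col, int) else 0
        amp_col = dialect.amplitude_col if isinstance(dialect.amplitude_col, int) else 1
        beam_col: int | None
        if isinstance(dialect.beam_on_col, int):
            beam_col = dialect.beam_on_col
        else:
            beam_col = 2 if df.shape[1] > 2 else None
    else:
        time_col, amp_col, beam_col = (
            dialect.time_col,
            dialect.amplitude_col,
            dialect.beam_on_col,
        )
    times = _pick_column(df, time_col, "time").to_numpy(dtype=float)
    amps = _pick_column(df, amp_col, "amplitude").to_numpy(dtype=float)
    beam_on = None
    if beam_col is not None:
        try:
            beam = _pick_column(df, beam_col, "beam_on")
        except FormatError:
            beam = None  # beam-on channel is optional
        if beam is not None:
            beam_on = beam.to_numpy(dtype=float).astype(bool)
    return BreathingSignal(
        times=times,
        amplitudes=amps,
        beam_on=beam_on,
        curve_id=curve_id if curve_id is not None else path.stem,
    )


def write_breathing_curve(signal: BreathingSignal, path: str | Path) -> None:
    """Write ``signal`` in the default dialect.

    Floats are written with ``repr`` (shortest round-trip form), so
    write -> read -> write is byte-stable and read(write(x)) reproduces
    the arrays exactly.
    """
    path = Path(path)
    buf = io.StringIO()
    if signal.beam_on is None:
        buf.write("time_s,amplitude\n")
        for t, a in zip(signal.times, signal.amplitudes):
            buf.write(f"{float(t)!r},{float(a)!r}\n")
    else:
        buf.write("time_s,amplitude,beam_on\n")
        for t, a, b in zip(signal.times, signal.amplitudes, signal.beam_on):
            buf.write(f"{float(t)!r},{float(a)!r},{int(b)}\n")
    path.write_text(buf.getvalue())


def beam_on_intervals_from_flags(signal: BreathingSignal) -> BeamOnIntervals:
    """Convert per-sample beam-on flags into half-open time intervals.

    A run of true flags from sample ``i`` to ``j`` (inclusive) maps to
    ``[times[i], times[i] + run_length * dt)`` so the total beam-on
    duration is exactly the number of true flags times the sample
    period.
    """
    if signal.beam_on is None:
        raise MissingChannelError("signal has no beam_on channel")
    flags = signal.beam_on
    dt = signal.sample_period
    # run starts/ends via flag transitions
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # ends are exclusive indices
    intervals = [
        (float(signal.times[i]), float(signal.times[i]) + (j - i) * dt)
        for i, j in zip(starts, ends)
    ]
    return BeamOnIntervals(intervals)
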