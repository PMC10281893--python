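"""Seeded synthetic breathing-signal generator with ground truth.

The generator emulates the irregularity classes that degrade 4D CT image
quality: cycle-to-cycle amplitude variability, breathing-frequency
variability, breathing pauses, linear baseline drift and additive
measurement noise.  Each breathing cycle follows the standard cos-power
respiratory surrogate

    baseline + a_i * cos^(2m)(pi * (t - t_peak_i) / tau_i)

which has a single end-inhalation peak per cycle and a realistic dwell
near end-exhalation for even exponents.  Cycles are concatenated
continuously at the end-exhale baseline: the rising limb into peak ``i``
and the falling limb out of it both carry that cycle's amplitude
``a_i``, and neighbouring limbs meet at amplitude zero.  Pauses hold the
end-exhale baseline flat.  Peak times land exactly on the sample grid,
so on a noise-free signal every generated peak is a strict sampled local
maximum of exactly its drawn height.

Ground truth carries both the *drawn* peak heights (the generative
amplitudes) and the *realized* per-cycle peak-to-peak amplitudes, i.e.
max - min of the clean sampled signal over each half-open peak-to-peak
interval.  The realized values are what an ideal analysis of this exact
signal would measure; see docs/methods.md for why the two differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import DegenerateSpecError, IntervalRangeError, ValidationError
from .signal_io import BeamOnIntervals, BreathingSignal


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic breathing curve.

    Durations/periods in seconds, amplitudes in arbitrary units (a.u.),
    ``drift_slope`` in a.u./s.  ``pauses`` is a list of
    ``(insert_after_cycle_index, pause_duration_s)`` pairs; the pause is
    inserted at the end-exhale trough following that (0-based) cycle.
    """

    duration_s: float = 120.0
    sample_rate: float = 25.0
    period_mean_s: float = 4.0
    period_sd_s: float = 0.4
    amp_mean: float = 1.0
    amp_sd: float = 0.15
    shape_exponent: int = 2
    pauses: list[tuple[int, float]] = field(default_factory=list)
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    curve_id: str = ""

    def __post_init__(self) -> None:
        if self.period_mean_s <= 0:
            raise ValidationError("period_mean_s must be positive")
        if self.amp_mean <= 0:
            raise ValidationError("amp_mean must be positive")
        if min(self.period_sd_s, self.amp_sd, self.noise_sd) < 0:
            raise ValidationError("sd values must be non-negative")
        if self.shape_exponent < 1:
            raise ValidationError("shape_exponent must be a positive integer")
        if any(d <= 0 for _, d in self.pauses):
            raise ValidationError("pause durations must be positive")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pauses"] = [[int(i), float(p)] for i, p in self.pauses]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["pauses"] = [(int(i), float(p)) for i, p in d.get("pauses", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """True cycle structure of a generated signal.

    ``peak_heights`` are the drawn generative amplitudes a_i;
    ``cycle_amplitudes`` are the realized clean per-interval
    peak-to-peak amplitudes over the half-open peak-to-peak intervals.
    ``true_mean_period_s`` is the median inter-peak duration (the
    pause-robust location the analysis targets).
    """

    peak_times_s: np.ndarray
    peak_heights: np.ndarray
    cycle_intervals: list[tuple[float, float]]
    cycle_amplitudes: np.ndarray
    pause_intervals: list[tuple[float, float]]
    true_amp_sd: float
    true_mean_period_s: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_intervals)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    """One truncated-normal draw by rejection (exact, seeded)."""
    if sd == 0.0:
        return max(mean, lower)
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return x
    raise DegenerateSpecError("truncated-normal rejection failed; check mean/sd")


def generate_signal(spec: SyntheticSpec) -> tuple[BreathingSignal, GroundTruth]:
    """Generate a synthetic breathing curve with ground truth.

    Deterministic for a fixed ``spec.seed``.  The returned trace length
    is ``duration_s`` plus the total inserted pause time, to within one
    sample period.
    """
    if spec.duration_s < spec.period_mean_s:
        raise DegenerateSpecError(
            "duration_s shorter than one mean breathing period"
        )
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    pause_after = {int(i): float(d) for i, d in spec.pauses}
    total_pause_s = 0.0

    # Build the clean (no drift, no noise) trace sample by segment.
    # Half-cycle lengths are rounded to whole samples so peaks and
    # troughs land exactly on the grid.
    clean: list[np.ndarray] = []
    peak_indices: list[int] = []
    peak_heights: list[float] = []
    pause_spans: list[tuple[int, int]] = []  # sample-index half-open
    n_target = int(round(spec.duration_s / dt))
    pos = 0  # next sample index to fill; current value is baseline 0
    cycle = 0
    while pos < n_target + int(round(total_pause_s / dt)):
        tau = _trunc_normal(
            rng, spec.period_mean_s, spec.period_sd_s, 0.5 * spec.period_mean_s
        )
        a = _trunc_normal(rng, spec.amp_mean, spec.amp_sd, 0.0)
        half = max(1, int(round(0.5 * tau / dt)))
        tau_eff = 2 * half * dt
        # rising limb: samples pos..pos+half-1 (trough at pos, value 0),
        # peak at pos+half; falling limb: peak+1 .. peak+half-1; the
        # trough sample at peak+half starts the next segment.
        k = np.arange(1, 2 * half)  # offsets from trough, peak at k=half
        vals = a * np.cos(np.pi * (k - half) * dt / tau_eff) ** (2 * spec.shape_exponent)
        seg = np.concatenate([[0.0], vals])  # trough sample + limbs
        clean.append(seg)
        peak_indices.append(pos + half)
        peak_heights.append(a)
        pos += 2 * half
        if cycle in pause_after:
            n_pause = max(1, int(round(pause_after[cycle] / dt)))
            clean.append(np.zeros(n_pause))
            pause_spans.append((pos, pos + n_pause))
            pos += n_pause
            total_pause_s += n_pause * dt
        cycle += 1

    x = np.concatenate(clean)
    n_total = n_target + int(round(total_pause_s / dt))
    if len(x) < n_total:
        x = np.concatenate([x, np.zeros(n_total - len(x))])
    x = x[:n_total]
    times = np.arange(n_total) * dt

    # a peak on the final sample has no falling limb and is not an
    # observable (interior) local maximum, so it is not counted
    kept_peaks = [i for i in peak_indices if i < n_total - 1]
    kept_heights = [h for i, h in zip(peak_indices, peak_heights) if i < n_total - 1]
    if len(kept_peaks) < 2:
        raise DegenerateSpecError("spec yields fewer than two breathing cycles")

    peak_times = times[kept_peaks]
    intervals = [
        (float(peak_times[i]), float(peak_times[i + 1]))
        for i in range(len(peak_times) - 1)
    ]
    # realized per-interval peak-to-peak amplitude on the clean trace
    realized = np.array(
        [
            float(np.max(x[p:q]) - np.min(x[p:q]))
            for p, q in zip(kept_peaks[:-1], kept_peaks[1:])
        ]
    )
    gaps = np.diff(peak_times)
    truth = GroundTruth(
        peak_times_s=peak_times,
        peak_heights=np.array(kept_heights),
        cycle_intervals=intervals,
        cycle_amplitudes=realized,
        pause_intervals=[
            (float(times[s]), float(times[s]) + (e - s) * dt)
            for s, e in pause_spans
            if e <= n_total
        ],
        true_amp_sd=float(np.std(realized, ddof=1)) if len(realized) > 1 else 0.0,
        true_mean_period_s=float(np.median(gaps)),
    )

    amplitudes = x + spec.drift_slope * times
    if spec.noise_sd > 0:
        amplitudes = amplitudes + rng.normal(0.0, spec.noise_sd, n_total)
    signal = BreathingSignal(
        times=times, amplitudes=amplitudes, curve_id=spec.curve_id
    )
    return signal, truth


def attach_beam_on(
    signal: BreathingSignal, intervals: BeamOnIntervals
) -> BreathingSignal:
    """Stamp beam-on flags onto a signal from explicit intervals.

    A sample is flagged on iff its time lies in some half-open interval.
    Intervals must lie within ``[t0, t_last + dt)``.
    """
    t0 = float(signal.times[0])
    t_end = float(signal.times[-1]) + signal.sample_period
    for start, end in intervals.intervals:
        if start < t0 - 1e-12 or end > t_end + 1e-12:
            raise IntervalRangeError(
                f"interval [{start}, {end}) outside signal range [{t0}, {t_end})"
            )
    flags = intervals.contains(signal.times)
    return BreathingSignal(
        times=signal.times.copy(),
        amplitudes=signal.amplitudes.copy(),
        beam_on=flags,
        curve_id=signal.curve_id,
    )
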