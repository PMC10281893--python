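"""Breathing-irregularity statistics, cohort selection and matching.

Two statistics drive everything:

* ``amp_p2p_sd`` -- the sample standard deviation (n-1 denominator) of
  the per-cycle peak-to-peak amplitudes, computed after beam-on
  windowing, linear drift correction and unit-range normalization, so
  it is a dimensionless fraction of the total respiratory excursion.
* breathing pauses -- inter-peak durations at least ``factor`` (default
  1.5) times the patient's average breathing cycle (median inter-peak
  duration).  The pause duration is the full inter-peak gap and its
  start is the earlier peak of the gap.

The most irregular curves of a cohort are the top ``n_amp`` (default
15) by amplitude variability plus, among the remainder, the top
``n_pause`` (default 10) by longest pause -- a disjoint 15+10 split.  A
second cohort is matched to the selection by greedy nearest-neighbour
search without replacement on the respective statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cycles import CycleSegmentation
from .errors import InsufficientCyclesError, SizeError
from .rank_stats import TestResult, mann_whitney_u


@dataclass
class IrregularityMetrics:
    """Irregularity statistics for one breathing curve."""

    curve_id: str
    amp_p2p_sd: float
    pauses: list[tuple[float, float]]  # (start_s, duration_s)
    longest_pause_s: float
    mean_cycle_s: float
    n_cycles: int

    def to_dict(self) -> dict:
        return {
            "curve_id": self.curve_id,
            "amp_p2p_sd": self.amp_p2p_sd,
            "pauses": [[s, d] for s, d in self.pauses],
            "longest_pause_s": self.longest_pause_s,
            "mean_cycle_s": self.mean_cycle_s,
            "n_cycles": self.n_cycles,
        }


@dataclass
class CohortSelection:
    """Ids of the most irregular curves of a cohort (disjoint lists)."""

    amp_selected: list[str]
    pause_selected: list[str]


@dataclass
class CohortMatch:
    """Greedy metric matching of a pool cohort to a reference selection."""

    pairs: list[tuple[str, str, str, float]]  # (ref_id, matched_id, criterion, distance)

    def total_distance(self) -> float:
        return float(sum(p[3] for p in self.pairs))


def amp_variability(seg: CycleSegmentation) -> float:
    """Sample SD (ddof=1) of the per-cycle peak-to-peak amplitudes."""
    if seg.n_cycles < 2:
        raise InsufficientCyclesError("amp variability needs >= 2 cycles")
    return float(np.std(seg.cycle_p2p_amplitudes, ddof=1))


def detect_pauses(
    seg: CycleSegmentation, factor: float = 1.5
) -> list[tuple[float, float]]:
    """Breathing pauses: inter-peak gaps >= factor * median cycle length.

    Returns ``(start_s, duration_s)`` per pause, start being the earlier
    peak of the gap.
    """
    if seg.n_cycles < 2:
        raise InsufficientCyclesError("pause detection needs >= 2 cycles")
    threshold = factor * seg.mean_cycle_s
    return [
        (float(seg.peak_times_s[i]), float(d))
        for i, d in enumerate(seg.inter_peak_durations_s)
        if d >= threshold
    ]


def compute_metrics(curve_id: str, seg: CycleSegmentation, factor: float = 1.5) -> IrregularityMetrics:
    """Bundle both irregularity statistics for one segmented curve."""
    pauses = detect_pauses(seg, factor=factor)
    return IrregularityMetrics(
        curve_id=curve_id,
        amp_p2p_sd=amp_variability(seg),
        pauses=pauses,
        longest_pause_s=max((d for _, d in pauses), default=0.0),
        mean_cycle_s=seg.mean_cycle_s,
        n_cycles=seg.n_cycles,
    )


def select_irregular_cohort(
    all_metrics: Sequence[IrregularityMetrics],
    n_amp: int = 15,
    n_pause: int = 10,
) -> CohortSelection:
    """Pick the n_amp + n_pause most irregular curves (disjoint).

    Amplitude criterion takes precedence; ties break by curve_id.
    """
    if len(all_metrics) < n_amp + n_pause:
        raise SizeError(
            f"cohort of {len(all_metrics)} too small for {n_amp}+{n_pause} selection"
        )
    by_amp = sorted(all_metrics, key=lambda m: (-m.amp_p2p_sd, m.curve_id))
    amp_ids = [m.curve_id for m in by_amp[:n_amp]]
    rest = [m for m in all_metrics if m.curve_id not in set(amp_ids)]
    by_pause = sorted(rest, key=lambda m: (-m.longest_pause_s, m.curve_id))
    pause_ids = [m.curve_id for m in by_pause[:n_pause]]
    return CohortSelection(amp_selected=amp_ids, pause_selected=pause_ids)


def match_cohorts(
    selection: CohortSelection,
    reference_metrics: Sequence[IrregularityMetrics],
    pool: Sequence[IrregularityMetrics],
) -> CohortMatch:
    """Greedy nearest-neighbour matching without replacement.

    Reference curves are processed in descending order of their
    selection statistic; each takes the unmatched pool curve minimizing
    the absolute difference in that statistic (amp_p2p_sd for
    amplitude-selected, longest_pause_s for pause-selected).
    """
    n_needed = len(selection.amp_selected) + len(selection.pause_selected)
    if len(pool) < n_needed:
        raise SizeError(f"pool of {len(pool)} cannot match {n_needed} references")
    ref_by_id = {m.curve_id: m for m in reference_metrics}
    available = {m.curve_id: m for m in pool}
    pairs: list[tuple[str, str, str, float]] = []

    def run(ids: list[str], key, criterion: str) -> None:
        ordered = sorted(ids, key=lambda i: (-key(ref_by_id[i]), i))
        for rid in ordered:
            if not available:
                raise SizeError("matching pool exhausted")
            target = key(ref_by_id[rid])
            best = min(
                available.values(), key=lambda m: (abs(key(m) - target), m.curve_id)
            )
            pairs.append(
                (rid, best.curve_id, criterion, abs(key(best) - target))
            )
            del available[best.curve_id]

    run(selection.amp_selected, lambda m: m.amp_p2p_sd, "amp")
    run(selection.pause_selected, lambda m: m.longest_pause_s, "pause")
    return CohortMatch(pairs=pairs)


def cohort_summary(
    metrics_a: Sequence[IrregularityMetrics],
    metrics_b: Sequence[IrregularityMetrics],
) -> dict:
    """Cross-cohort summary: medians of both statistics per cohort plus
    two-sided Mann-Whitney U p-values."""
    if not metrics_a or not metrics_b:
        raise SizeError("cohort summary needs two non-empty cohorts")
    amp_a = [m.amp_p2p_sd for m in metrics_a]
    amp_b = [m.amp_p2p_sd for m in metrics_b]
    pause_a = [m.longest_pause_s for m in metrics_a]
    pause_b = [m.longest_pause_s for m in metrics_b]
    mw_amp = mann_whitney_u(amp_a, amp_b)
    mw_pause = mann_whitney_u(pause_a, pause_b)
    return {
        "median_amp_p2p_sd": {
            "a": float(np.median(amp_a)),
            "b": float(np.median(amp_b)),
        },
        "median_longest_pause_s": {
            "a": float(np.median(pause_a)),
            "b": float(np.median(pause_b)),
        },
        "mann_whitney": {
            "amp_p2p_sd": {"U": mw_amp.statistic, "p": mw_amp.p_value},
            "longest_pause_s": {"U": mw_pause.statistic, "p": mw_pause.p_value},
        },
    }
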