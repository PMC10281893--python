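"""Irregularity metrics, cohort selection, matching and summaries."""

import numpy as np
import pytest

from breath4dct import (
    CohortSelection,
    IrregularityMetrics,
    SyntheticSpec,
    amp_variability,
    cohort_summary,
    compute_metrics,
    detect_inhalation_peaks,
    detect_pauses,
    generate_signal,
    match_cohorts,
    preprocess,
    segment_cycles,
    select_irregular_cohort,
)
from breath4dct.cycles import CycleSegmentation
from breath4dct.errors import InsufficientCyclesError, SizeError


def _seg(peak_times, p2p):
    """Build a CycleSegmentation directly from peak times and p2p values."""
    peak_times = np.asarray(peak_times, float)
    gaps = np.diff(peak_times)
    return CycleSegmentation(
        peak_times_s=peak_times,
        cycle_intervals=[
            (float(a), float(b)) for a, b in zip(peak_times[:-1], peak_times[1:])
        ],
        cycle_p2p_amplitudes=np.asarray(p2p, float),
        inter_peak_durations_s=gaps,
        mean_cycle_s=float(np.median(gaps)),
    )


def _metrics(curve_id, amp_sd, longest_pause):
    return IrregularityMetrics(
        curve_id=curve_id,
        amp_p2p_sd=amp_sd,
        pauses=[(0.0, longest_pause)] if longest_pause > 0 else [],
        longest_pause_s=longest_pause,
        mean_cycle_s=4.0,
        n_cycles=30,
    )


class TestAmpVariability:
    def test_two_point_closed_form(self):
        # SD of {0.9, 1.1} with ddof=1 is sqrt(0.02)
        seg = _seg([0, 4, 8, 12], [0.9, 1.1, 1.0])
        assert amp_variability(_seg([0, 4, 8], [0.9, 1.1])) == pytest.approx(
            np.sqrt(0.02)
        )
        assert amp_variability(seg) == pytest.approx(0.1)

    def test_needs_two_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            amp_variability(_seg([0, 4], [1.0]))


class TestPauseDetection:
    def test_threshold_is_inclusive_factor_times_median(self):
        # median gap 4 s -> threshold 6 s; 5 s gap no, 6 s gap yes
        seg = _seg([0, 4, 8, 13, 17, 23, 27], np.ones(6))
        pauses = detect_pauses(seg, factor=1.5)
        assert pauses == [(17.0, 6.0)]

    def test_regular_breathing_has_no_pauses(self, regular_signal):
        signal, _ = regular_signal
        pre = preprocess(signal)
        seg = segment_cycles(pre, detect_inhalation_peaks(pre))
        assert detect_pauses(seg) == []

    def test_inserted_pause_detected_with_gap_accounting(self):
        """The detected gap spans hold + following period."""
        spec = SyntheticSpec(
            duration_s=120, period_sd_s=0.0, amp_sd=0.0, noise_sd=0.0,
            pauses=[(5, 8.0)], seed=7,
        )
        signal, truth = generate_signal(spec)
        pre = preprocess(signal)
        seg = segment_cycles(pre, detect_inhalation_peaks(pre))
        pauses = detect_pauses(seg)
        assert len(pauses) == 1
        start, dur = pauses[0]
        # the inter-peak gap is the 8 s hold plus one ordinary cycle
        assert dur == pytest.approx(8.0 + 4.0, abs=2 * signal.sample_period)
        p_start, _ = truth.pause_intervals[0]
        assert start <= p_start <= start + dur

    def test_compute_metrics_bundles_both(self, irregular_signal):
        signal, _ = irregular_signal
        pre = preprocess(signal)
        seg = segment_cycles(pre, detect_inhalation_peaks(pre))
        m = compute_metrics("x", seg)
        assert m.amp_p2p_sd == pytest.approx(amp_variability(seg))
        assert m.longest_pause_s == max((d for _, d in m.pauses), default=0.0)
        assert m.n_cycles == seg.n_cycles
        assert m.to_dict()["curve_id"] == "x"


class TestSelection:
    def _pool(self):
        rng = np.random.default_rng(5)
        return [
            _metrics(f"c{i:02d}", float(rng.uniform(0, 0.5)), float(rng.uniform(0, 12)))
            for i in range(40)
        ]

    def test_matches_sort_oracle_and_is_disjoint(self):
        pool = self._pool()
        sel = select_irregular_cohort(pool, n_amp=15, n_pause=10)
        amp_order = sorted(pool, key=lambda m: (-m.amp_p2p_sd, m.curve_id))
        assert sel.amp_selected == [m.curve_id for m in amp_order[:15]]
        rest = [m for m in pool if m.curve_id not in set(sel.amp_selected)]
        pause_order = sorted(rest, key=lambda m: (-m.longest_pause_s, m.curve_id))
        assert sel.pause_selected == [m.curve_id for m in pause_order[:10]]
        assert not set(sel.amp_selected) & set(sel.pause_selected)
        assert len(sel.amp_selected) == 15 and len(sel.pause_selected) == 10

    def test_cohort_too_small(self):
        with pytest.raises(SizeError):
            select_irregular_cohort(self._pool()[:20], n_amp=15, n_pause=10)


class TestMatching:
    def test_exact_duplicates_match_at_zero_distance(self):
        ref = [_metrics(f"r{i}", 0.1 * i, float(i)) for i in range(1, 6)]
        pool = [_metrics(f"p{i}", 0.1 * i, float(i)) for i in range(1, 6)]
        sel = CohortSelection(
            amp_selected=[m.curve_id for m in ref[:3]],
            pause_selected=[m.curve_id for m in ref[3:]],
        )
        match = match_cohorts(sel, ref, pool)
        assert match.total_distance() == 0.0
        assert {(r, m) for r, m, _, _ in match.pairs} == {
            (f"r{i}", f"p{i}") for i in range(1, 6)
        }

    def test_nearest_neighbour_choice(self):
        ref = [_metrics("r1", 0.39, 0.0)]
        pool = [
            _metrics("p_lo", 0.30, 0.0),
            _metrics("p_hi", 0.38, 0.0),
            _metrics("p_far", 0.70, 0.0),
        ]
        sel = CohortSelection(amp_selected=["r1"], pause_selected=[])
        match = match_cohorts(sel, ref, pool)
        assert match.pairs[0][1] == "p_hi"
        assert match.pairs[0][3] == pytest.approx(0.01)

    def test_greedy_beats_random_assignment(self):
        rng = np.random.default_rng(42)
        ref = [_metrics(f"r{i:02d}", float(rng.uniform(0, 0.5)), float(rng.uniform(0, 12))) for i in range(25)]
        pool = [_metrics(f"p{i:02d}", float(rng.uniform(0, 0.5)), float(rng.uniform(0, 12))) for i in range(40)]
        sel = CohortSelection(
            amp_selected=[m.curve_id for m in ref[:15]],
            pause_selected=[m.curve_id for m in ref[15:]],
        )
        greedy = match_cohorts(sel, ref, pool).total_distance()
        ref_by_id = {m.curve_id: m for m in ref}
        for _ in range(1000):
            chosen = rng.choice(len(pool), size=25, replace=False)
            total = 0.0
            for rid, j in zip(sel.amp_selected + sel.pause_selected, chosen):
                r = ref_by_id[rid]
                p = pool[j]
                if rid in sel.amp_selected:
                    total += abs(p.amp_p2p_sd - r.amp_p2p_sd)
                else:
                    total += abs(p.longest_pause_s - r.longest_pause_s)
            assert greedy <= total + 1e-12

    def test_pool_too_small(self):
        ref = [_metrics("r1", 0.1, 0.0), _metrics("r2", 0.2, 0.0)]
        sel = CohortSelection(amp_selected=["r1", "r2"], pause_selected=[])
        with pytest.raises(SizeError):
            match_cohorts(sel, ref, [_metrics("p1", 0.1, 0.0)])


class TestCohortSummary:
    def test_identical_cohorts_give_high_p(self):
        a = [_metrics(f"a{i}", 0.1 * i, float(i)) for i in range(1, 9)]
        b = [_metrics(f"b{i}", 0.1 * i, float(i)) for i in range(1, 9)]
        out = cohort_summary(a, b)
        assert out["median_amp_p2p_sd"]["a"] == out["median_amp_p2p_sd"]["b"]
        assert out["mann_whitney"]["amp_p2p_sd"]["p"] == pytest.approx(1.0, abs=0.05)

    def test_shifted_cohort_moves_median_and_p(self):
        a = [_metrics(f"a{i}", 0.02 * i, float(i)) for i in range(1, 13)]
        b = [_metrics(f"b{i}", 0.02 * i, float(i) + 20.0) for i in range(1, 13)]
        out = cohort_summary(a, b)
        assert (
            out["median_longest_pause_s"]["b"]
            == out["median_longest_pause_s"]["a"] + 20.0
        )
        # fully separated shift on 12-vs-12 should be significant
        assert out["mann_whitney"]["longest_pause_s"]["p"] < 0.05

    def test_empty_cohort_rejected(self):
        with pytest.raises(SizeError):
            cohort_summary([], [_metrics("b", 0.1, 0.0)])
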