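"""Acquisition simulation: spiral vs breathing-adapted sequence."""

import numpy as np
import pytest

from breath4dct import (
    ScanConfig,
    SyntheticSpec,
    artifact_proxy,
    assign_phase,
    compare_protocols,
    detect_inhalation_peaks,
    generate_signal,
    preprocess,
    segment_cycles,
    sequence_preset,
    simulate_sequence_i4dct,
    simulate_spiral,
    spiral_preset,
)
from breath4dct.acquisition import _positions
from breath4dct.errors import (
    EmptyResultError,
    InsufficientSignalError,
    LearningError,
    ValidationError,
)


def _analyze(signal):
    pre = preprocess(signal)
    seg = segment_cycles(pre, detect_inhalation_peaks(pre))
    phases = assign_phase(pre, seg)
    return pre, seg, phases


@pytest.fixture(scope="module")
def regular_scan(regular_signal):
    return _analyze(regular_signal[0])


@pytest.fixture(scope="module")
def irregular_scan(irregular_signal):
    return _analyze(irregular_signal[0])


class TestScanConfig:
    def test_derived_quantities(self):
        cfg = spiral_preset()
        assert cfg.collimation_mm == pytest.approx(19.2)
        assert cfg.couch_speed_mm_s == pytest.approx(0.09 * 19.2 / 0.5)
        assert cfg.illumination_window_s == pytest.approx(0.5 / 0.09)
        seq = sequence_preset()
        assert seq.collimation_mm == pytest.approx(38.4)
        assert seq.couch_increment_mm == pytest.approx(34.56)

    def test_validation(self):
        with pytest.raises(ValidationError):
            ScanConfig(mode="helical")
        with pytest.raises(ValidationError):
            ScanConfig(mode="spiral", pitch=0.0)
        with pytest.raises(ValidationError):
            ScanConfig(mode="sequence", couch_increment_mm=100.0)
        with pytest.raises(ValidationError):
            ScanConfig(mode="spiral", fov_length_mm=-1.0)

    def test_position_grid(self):
        pos = _positions(150.0, 19.2)
        assert len(pos) == int(np.ceil(150.0 / 19.2))
        np.testing.assert_allclose(np.diff(pos), 19.2)
        assert pos[0] == pytest.approx(9.6)
        assert len(_positions(0.0, 19.2)) == 0


class TestSpiral:
    def test_regular_breathing_full_coverage(self, regular_scan):
        pre, seg, phases = regular_scan
        res = simulate_spiral(pre, seg, phases, spiral_preset())
        assert res.n_missing == 0
        prox = artifact_proxy(res, pre, seg)
        assert prox.interpolation_count == 0
        assert prox.double_structure_score < 0.05

    def test_scan_duration_and_duty(self, regular_scan):
        pre, seg, phases = regular_scan
        cfg = spiral_preset()
        res = simulate_spiral(pre, seg, phases, cfg)
        assert res.scan_duration_s == pytest.approx(150.0 / cfg.couch_speed_mm_s)
        assert res.beam_duty_cycle == 1.0
        assert len(res.beam_on) == 1  # continuous irradiation

    def test_selected_samples_lie_in_position_windows(self, irregular_scan):
        pre, seg, phases = irregular_scan
        res = simulate_spiral(pre, seg, phases, spiral_preset())
        for k, (w_lo, w_hi) in enumerate(res.per_position_intervals):
            row = res.coverage_times[k]
            covered = row[~np.isnan(row)]
            assert np.all(covered >= w_lo - 1e-9)
            assert np.all(covered < w_hi + 1e-9)

    def test_pause_causes_missing_bins(self):
        # a pause longer than the illumination window starves phase bins
        spec = SyntheticSpec(
            duration_s=240, period_sd_s=0.0, amp_sd=0.0, noise_sd=0.0,
            pauses=[(8, 10.0)], seed=3,
        )
        pre, seg, phases = _analyze(generate_signal(spec)[0])
        res = simulate_spiral(pre, seg, phases, spiral_preset())
        assert res.n_missing > 0

    def test_too_short_signal_rejected(self):
        spec = SyntheticSpec(duration_s=40, seed=1)
        pre, seg, phases = _analyze(generate_signal(spec)[0])
        with pytest.raises(InsufficientSignalError):
            simulate_spiral(pre, seg, phases, spiral_preset())

    def test_zero_fov_is_empty_result(self, regular_scan):
        pre, seg, phases = regular_scan
        res = simulate_spiral(pre, seg, phases, spiral_preset(fov_length_mm=0.0))
        assert res.coverage_times.size == 0
        with pytest.raises(EmptyResultError):
            artifact_proxy(res, pre, seg)

    def test_wrong_mode_rejected(self, regular_scan):
        pre, seg, phases = regular_scan
        with pytest.raises(ValidationError):
            simulate_spiral(pre, seg, phases, sequence_preset())


class TestSequence:
    def test_regular_breathing_full_coverage(self, regular_scan):
        pre, seg, phases = regular_scan
        res = simulate_sequence_i4dct(pre, seg, phases, sequence_preset())
        assert res.n_missing == 0
        assert res.incomplete_positions == []
        prox = artifact_proxy(res, pre, seg)
        assert prox.double_structure_score < 0.05

    def test_dwell_close_to_one_period_plus_rotation(self, regular_scan):
        """With regular 4 s breathing the first acceptable cycle follows
        immediately, so each dwell is ~ period + rotation_time."""
        pre, seg, phases = regular_scan
        cfg = sequence_preset()
        res = simulate_sequence_i4dct(pre, seg, phases, cfg)
        dt = pre.sample_period
        for s, e in res.per_position_intervals:
            assert e - s == pytest.approx(4.0 + cfg.rotation_time_s, abs=3 * dt)

    def test_duty_cycle_below_one_with_dead_time(self, regular_scan):
        pre, seg, phases = regular_scan
        res = simulate_sequence_i4dct(pre, seg, phases, sequence_preset())
        assert 0.0 < res.beam_duty_cycle < 1.0
        # duty = on / span with span including dead times
        on = sum(e - s for s, e in res.per_position_intervals)
        span = res.per_position_intervals[-1][1] - res.per_position_intervals[0][0]
        assert res.beam_duty_cycle == pytest.approx(on / span)
        assert res.scan_duration_s == pytest.approx(span)

    def test_intervals_are_ordered_and_disjoint(self, irregular_scan):
        pre, seg, phases = irregular_scan
        res = simulate_sequence_i4dct(pre, seg, phases, sequence_preset())
        iv = res.per_position_intervals
        assert len(iv) == len(res.couch_positions_mm)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            assert e1 <= s2 + 1e-12

    def test_vacuous_tolerances_accept_first_cycle(self, irregular_scan):
        """Infinite tolerances reduce gating to 'first completed cycle'."""
        pre, seg, phases = irregular_scan
        cfg = sequence_preset()
        cfg.amp_tolerance = np.inf
        cfg.period_tolerance = np.inf
        res = simulate_sequence_i4dct(pre, seg, phases, cfg)
        assert res.incomplete_positions == []
        peaks = seg.peak_times_s
        for s, e in res.per_position_intervals:
            # dwell ends one rotation after the first peak confirmed
            # after beam-on
            nxt = peaks[np.searchsorted(peaks, s)]
            assert e == pytest.approx(
                nxt + pre.sample_period + cfg.rotation_time_s, abs=1e-9
            )

    def test_insufficient_learning_cycles(self):
        spec = SyntheticSpec(duration_s=12, seed=2)
        pre, seg, phases = _analyze(generate_signal(spec)[0])
        with pytest.raises((LearningError, InsufficientSignalError)):
            simulate_sequence_i4dct(pre, seg, phases, sequence_preset())

    def test_wrong_mode_rejected(self, regular_scan):
        pre, seg, phases = regular_scan
        with pytest.raises(ValidationError):
            simulate_sequence_i4dct(pre, seg, phases, spiral_preset())


class TestArtifactProxies:
    def test_interpolation_count_equals_nan_cells(self, irregular_scan):
        pre, seg, phases = irregular_scan
        res = simulate_spiral(pre, seg, phases, spiral_preset())
        prox = artifact_proxy(res, pre, seg)
        assert prox.interpolation_count == int(np.isnan(res.coverage_times).sum())

    def test_identical_rows_give_zero_score(self, regular_scan):
        pre, seg, phases = regular_scan
        res = simulate_spiral(pre, seg, phases, spiral_preset())
        # overwrite coverage so every position reuses the same samples
        res.coverage_times = np.tile(res.coverage_times[0], (len(res.couch_positions_mm), 1))
        prox = artifact_proxy(res, pre, seg)
        assert prox.double_structure_score == 0.0


class TestCompareProtocols:
    def test_report_structure(self, irregular_signal):
        signal, _ = irregular_signal
        report = compare_protocols(signal, spiral_preset(), sequence_preset())
        assert set(report["protocols"]) == {"spiral", "sequence"}
        for proto in report["protocols"].values():
            assert proto["n_positions"] > 0
            assert 0.0 < proto["beam_duty_cycle"] <= 1.0
            assert proto["interpolation_count"] >= 0
            assert proto["double_structure_score"] >= 0.0
        assert report["protocols"]["spiral"]["beam_duty_cycle"] == 1.0
        assert report["protocols"]["sequence"]["beam_duty_cycle"] < 1.0

    def test_sequence_resists_irregularity(self):
        """On a curve with a pause plus amplitude drift the sequence
        protocol keeps every cell filled while spiral loses some."""
        spec = SyntheticSpec(
            duration_s=300, period_sd_s=0.4, amp_sd=0.35, noise_sd=0.02,
            pauses=[(10, 10.0)], seed=77,
        )
        signal, _ = generate_signal(spec)
        report = compare_protocols(signal, spiral_preset(), sequence_preset())
        sp = report["protocols"]["spiral"]
        sq = report["protocols"]["sequence"]
        assert sq["interpolation_count"] <= sp["interpolation_count"]
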