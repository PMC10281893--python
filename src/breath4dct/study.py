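"""End-to-end desk-scale study on synthetic cohorts.

Mirrors the clinical study design with synthetic data: generate two
breathing-curve cohorts (one per virtual center), compute irregularity
metrics for every curve, select the most irregular reference curves
(n_amp by amplitude variability + n_pause by longest pause), match the
second cohort to the selection, simulate both acquisition protocols on
every curve of every matched pair, and summarize artifact proxies and
cross-cohort statistics.

Everything is deterministic given the master seed: per-curve child
seeds are derived with ``numpy.random.SeedSequence`` spawn keys
``(cohort_index, curve_index)``, so adding curves never reshuffles
existing ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .acquisition import ScanConfig, compare_protocols, sequence_preset, spiral_preset
from .cycles import detect_inhalation_peaks, segment_cycles
from .errors import Breath4DCTError, SizeError
from .irregularity import (
    IrregularityMetrics,
    cohort_summary,
    compute_metrics,
    match_cohorts,
    select_irregular_cohort,
)
from .preprocessing import preprocess
from .signal_io import BreathingSignal
from .synthetic import SyntheticSpec, generate_signal

SCHEMA_VERSION = 1

logger = logging.getLogger("breath4dct.study")


@dataclass
class CohortSpec:
    """Distribution of per-curve generator parameters for one cohort.

    Each curve draws its parameters uniformly from the stated ranges;
    with probability ``pause_probability`` a curve gets one inserted
    pause of uniform duration from ``pause_duration_range_s``.  Defaults
    emulate a routine radiotherapy-planning cohort: 3-5.5 s breathing
    periods, mild-to-strong cycle-amplitude variability, occasional
    multi-second pauses, slight baseline drift and sensor noise.
    """

    n_curves: int = 60
    duration_s: float = 240.0
    sample_rate: float = 25.0
    period_mean_range_s: tuple[float, float] = (3.0, 5.5)
    period_sd_range_s: tuple[float, float] = (0.1, 0.6)
    amp_mean: float = 1.0
    amp_sd_range: tuple[float, float] = (0.05, 0.45)
    pause_probability: float = 0.3
    pause_duration_range_s: tuple[float, float] = (5.0, 12.0)
    drift_slope_range: tuple[float, float] = (-0.002, 0.002)
    noise_sd: float = 0.02


@dataclass
class StudyConfig:
    """Configuration of a full synthetic comparison study."""

    cohort_a: CohortSpec = field(default_factory=CohortSpec)
    cohort_b: CohortSpec = field(default_factory=CohortSpec)
    n_amp: int = 15
    n_pause: int = 10
    fov_length_mm: float = 150.0
    n_phases: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, cs in (("cohort_a", self.cohort_a), ("cohort_b", self.cohort_b)):
            if cs.n_curves < self.n_amp + self.n_pause:
                raise SizeError(
                    f"{name} has {cs.n_curves} curves; "
                    f"needs >= {self.n_amp + self.n_pause}"
                )


def _child_seed(master_seed: int, cohort: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cohort, index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _draw_curve_spec(
    cohort_spec: CohortSpec, master_seed: int, cohort: int, index: int, prefix: str
) -> SyntheticSpec:
    seed = _child_seed(master_seed, cohort, index)
    rng = np.random.default_rng(seed)
    pauses: list[tuple[int, float]] = []
    n_expected_cycles = cohort_spec.duration_s / np.mean(cohort_spec.period_mean_range_s)
    if rng.uniform() < cohort_spec.pause_probability:
        after = int(rng.integers(2, max(3, int(n_expected_cycles * 0.7))))
        pauses.append((after, float(rng.uniform(*cohort_spec.pause_duration_range_s))))
    return SyntheticSpec(
        duration_s=cohort_spec.duration_s,
        sample_rate=cohort_spec.sample_rate,
        period_mean_s=float(rng.uniform(*cohort_spec.period_mean_range_s)),
        period_sd_s=float(rng.uniform(*cohort_spec.period_sd_range_s)),
        amp_mean=cohort_spec.amp_mean,
        amp_sd=float(rng.uniform(*cohort_spec.amp_sd_range)),
        pauses=pauses,
        drift_slope=float(rng.uniform(*cohort_spec.drift_slope_range)),
        noise_sd=cohort_spec.noise_sd,
        seed=seed,
        curve_id=f"{prefix}{index:03d}",
    )


def generate_cohort(
    cohort_spec: CohortSpec, master_seed: int, cohort: int, prefix: str
) -> list[tuple[SyntheticSpec, BreathingSignal]]:
    """Generate all curves of one cohort (specs and signals)."""
    out = []
    for i in range(cohort_spec.n_curves):
        spec = _draw_curve_spec(cohort_spec, master_seed, cohort, i, prefix)
        signal, _ = generate_signal(spec)
        out.append((spec, signal))
    return out


def analyze_curve(signal: BreathingSignal) -> IrregularityMetrics:
    """Preprocess -> segment -> irregularity metrics for one curve."""
    pre = preprocess(signal)
    peaks = detect_inhalation_peaks(pre)
    seg = segment_cycles(pre, peaks)
    return compute_metrics(signal.curve_id, seg)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the full study and write its JSON outputs to ``out_dir``.

    Outputs: metrics_a.json / metrics_b.json (per-curve irregularity
    metrics), selection.json, match.json, comparison.json (per-pair
    paired-protocol simulation), summary.json (cohort medians and
    Mann-Whitney results) and run_log.txt.  All JSON is byte-stable for
    a fixed config; timestamps appear in the log only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    logger.info("run_study start (config hash %s)", config_hash)
    try:
        cohort_a = generate_cohort(config.cohort_a, config.master_seed, 0, "A")
        cohort_b = generate_cohort(config.cohort_b, config.master_seed, 1, "B")
        signals = {s.curve_id: s for _, s in cohort_a + cohort_b}
        metrics_a = [analyze_curve(s) for _, s in cohort_a]
        metrics_b = [analyze_curve(s) for _, s in cohort_b]
        for name, metrics in (("metrics_a", metrics_a), ("metrics_b", metrics_b)):
            p = out_dir / f"{name}.json"
            _write_json(
                p,
                {
                    "schema_version": SCHEMA_VERSION,
                    "curves": [m.to_dict() for m in metrics],
                },
            )
            written.append(p)

        selection = select_irregular_cohort(
            metrics_a, n_amp=config.n_amp, n_pause=config.n_pause
        )
        p = out_dir / "selection.json"
        _write_json(
            p,
            {
                "schema_version": SCHEMA_VERSION,
                "amp_selected": selection.amp_selected,
                "pause_selected": selection.pause_selected,
            },
        )
        written.append(p)

        match = match_cohorts(selection, metrics_a, metrics_b)
        p = out_dir / "match.json"
        _write_json(
            p,
            {
                "schema_version": SCHEMA_VERSION,
                "pairs": [
                    {
                        "reference_id": r,
                        "matched_id": m,
                        "criterion": c,
                        "metric_distance": d,
                    }
                    for r, m, c, d in match.pairs
                ],
                "total_distance": match.total_distance(),
            },
        )
        written.append(p)

        spiral_cfg = spiral_preset(config.fov_length_mm, config.n_phases)
        seq_cfg = sequence_preset(config.fov_length_mm, config.n_phases)
        comparisons = []
        for ref_id, match_id, criterion, _ in match.pairs:
            pair_report = {"criterion": criterion, "curves": {}}
            for role, cid in (("reference", ref_id), ("matched", match_id)):
                pair_report["curves"][role] = compare_protocols(
                    signals[cid], spiral_cfg, seq_cfg, n_phases=config.n_phases
                )
            comparisons.append(pair_report)
        p = out_dir / "comparison.json"
        _write_json(
            p, {"schema_version": SCHEMA_VERSION, "pairs": comparisons}
        )
        written.append(p)

        ref_ids = set(selection.amp_selected) | set(selection.pause_selected)
        match_ids = {m for _, m, _, _ in match.pairs}
        summary = cohort_summary(
            [m for m in metrics_a if m.curve_id in ref_ids],
            [m for m in metrics_b if m.curve_id in match_ids],
        )
        summary["schema_version"] = SCHEMA_VERSION
        summary["config_hash"] = config_hash
        p = out_dir / "summary.json"
        _write_json(p, summary)
        written.append(p)

        log_path = out_dir / "run_log.txt"
        log_path.write_text(
            f"breath4dct {__version__}\n"
            f"config hash: {config_hash}\n"
            f"cohort A: {len(cohort_a)} curves, cohort B: {len(cohort_b)} curves\n"
            f"selection: {config.n_amp} amp + {config.n_pause} pause\n"
            f"pairs simulated: {len(match.pairs)}\n"
        )
        logger.info("run_study finished: %d pairs", len(match.pairs))
        return {
            "selection": selection,
            "match": match,
            "comparisons": comparisons,
            "summary": summary,
            "out_dir": str(out_dir),
        }
    except Breath4DCTError:
        for p in written:
            p.unlink(missing_ok=True)  # no partial outputs on failure
        raise
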