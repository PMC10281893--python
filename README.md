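# breath4dct

Breathing-signal irregularity analysis and desk-scale simulation of two
4D CT acquisition strategies: conventional retrospectively gated
**spiral** scanning versus breathing-adapted **sequence** scanning
(i4DCT-style prospective gating).

## The problem

4D CT images the thorax as a series of 3-D volumes over the breathing
cycle. Conventional low-pitch spiral protocols move the couch
continuously and sort projection data into breathing-phase bins after
the scan. This works when breathing is regular; when it is not — cycles
of varying amplitude and length, or multi-second breathing pauses — the
fixed illumination window at each couch position may miss entire phase
bins (interpolation artifacts) or stitch inconsistent motion states at
adjacent positions (double structures). Breathing-adapted sequence
scanning instead steps the couch position by position and keeps the beam
on at each station until the real-time signal analysis has observed one
*representative* breathing cycle, so irregular cycles extend the scan
instead of corrupting the data.

This package provides:

- **Breathing-curve I/O** — plain-text CSV curves with optional per-sample
  beam-on flags (`breath4dct.signal_io`).
- **A synthetic breathing-curve generator** — cos-power waveform with
  per-cycle amplitude/period variability, end-exhale pauses, baseline
  drift and sensor noise, with exact ground truth (`breath4dct.synthetic`).
- **Preprocessing** — beam-on windowing, linear drift removal, unit-range
  normalization, with provenance so raw-unit quantities can be recovered
  (`breath4dct.preprocessing`).
- **Cycle analysis** — inhalation-peak detection, cycle segmentation and
  phase binning (`breath4dct.cycles`).
- **Irregularity metrics** — per-cycle peak-to-peak amplitude SD and
  breathing-pause detection (gaps ≥ 1.5× the median cycle), plus cohort
  selection (top 15 by amplitude variability + top 10 by longest pause)
  and greedy nearest-neighbour cohort matching (`breath4dct.irregularity`).
- **Acquisition simulation** — timing-accurate 1-D models of the spiral
  and sequence protocols with artifact-risk proxies
  (`breath4dct.acquisition`).
- **Self-contained rank statistics** — exact/asymptotic Mann-Whitney U,
  Spearman rank correlation, score summaries (`breath4dct.rank_stats`).
- **An end-to-end study driver** and a `breath4dct` command-line
  interface (`breath4dct.study`, `breath4dct.cli`).

See [docs/methods.md](docs/methods.md) for the models and their
assumptions.

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

```python
from breath4dct import (
    SyntheticSpec, generate_signal, preprocess, detect_inhalation_peaks,
    segment_cycles, compute_metrics, compare_protocols,
    spiral_preset, sequence_preset,
)

# an irregular breather: variable cycles plus one 8 s pause
spec = SyntheticSpec(
    duration_s=240, period_sd_s=0.4, amp_sd=0.35, noise_sd=0.02,
    pauses=[(10, 8.0)], seed=5, curve_id="demo",
)
signal, truth = generate_signal(spec)

pre = preprocess(signal)                      # window, de-drift, normalize
seg = segment_cycles(pre, detect_inhalation_peaks(pre))
metrics = compute_metrics("demo", seg)
print(metrics.n_cycles)        # 59
print(metrics.amp_p2p_sd)      # 0.1591  (normalized units)
print(metrics.longest_pause_s) # 11.84   (pause + the following cycle)

# back to raw units via the preprocessing provenance:
print(metrics.amp_p2p_sd * pre.provenance.scale)  # 0.2785, truth 0.2791

report = compare_protocols(signal, spiral_preset(), sequence_preset())
sp = report["protocols"]["spiral"]
sq = report["protocols"]["sequence"]
print(sp["interpolation_count"], sp["double_structure_score"])  # 3 0.185
print(sq["interpolation_count"], sq["double_structure_score"])  # 0 0.113
print(sp["beam_duty_cycle"], sq["beam_duty_cycle"])             # 1.0 0.731
```

On this curve the spiral protocol leaves 3 (position × phase) cells
without data and shows a higher adjacent-position amplitude mismatch,
while the breathing-adapted sequence protocol fills every cell at the
cost of a longer scan (77.9 s vs 43.4 s over a 150 mm field of view) and
a sub-unity duty cycle.

The same pipeline is available from the command line:

```bash
breath4dct simulate-signal --spec spec.yaml --out curve.csv
breath4dct analyze --in curve.csv --out metrics.json
breath4dct compare --curve curve.csv --spiral spiral.yaml \
    --sequence seq.yaml --out report.json
breath4dct run-study --out-dir study/ --seed 1
```

## License

MIT
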