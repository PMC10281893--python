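# Methods

This document describes the models implemented in `breath4dct`: the
synthetic breathing-curve generator, the preprocessing and cycle
analysis, the irregularity metrics and cohort procedures, the two
acquisition simulators with their artifact proxies, and the
rank-statistics implementation. Problem sizes (curve durations, cohort
sizes, field-of-view length) are the package's own desk-scale choices;
they are set so that every pipeline runs in seconds on one CPU while
still exercising all qualitative behaviour.

## 1. Synthetic breathing curves

### Waveform model

A breathing curve is built cycle by cycle as a baseline-anchored
cos-power bump:

```
x(t) = a_i * cos( pi * (t - p_i) / tau_i )^(2 m)
```

within the half-cycles adjacent to inhalation peak `i`, where `a_i` is
the drawn peak height, `p_i` the peak time, `tau_i` the cycle length and
`m` the shape exponent (default 2). Even powers of the cosine give the
characteristic breathing asymmetry — long, flat end-exhale plateaus near
the baseline and comparatively brief inhalation peaks — while keeping
the curve continuous and the baseline exactly zero between cycles.

The curve is constructed trough-to-trough on the sample grid so that
every inhalation peak falls **exactly on a sample**: each half-cycle
spans `max(1, round(0.5 * tau / dt))` samples. This makes noise-free
peak detection exact and lets the generator export exact ground truth.

Per-cycle lengths and peak heights are drawn from truncated normal
distributions (`period_mean_s ± period_sd_s`, `amp_mean ± amp_sd`,
truncated at zero via rejection sampling). Optional components, applied
in this order after the clean waveform is assembled:

1. **Breathing pauses**: after a chosen cycle index, the curve holds the
   end-exhale baseline for a given duration (samples inserted at zero).
2. **Linear drift**: `slope * t` added over the whole trace.
3. **Sensor noise**: i.i.d. Gaussian with SD `noise_sd`.

### Ground truth: drawn vs realized amplitudes

The generator reports two amplitude truths, and the distinction matters
for validating amplitude-variability estimates:

- `peak_heights`: the heights `a_i` drawn from the generator
  distribution.
- `cycle_amplitudes`: the *realized* clean peak-to-peak excursion of
  each peak-to-peak cycle interval `[p_i, p_{i+1})`.

They differ systematically. A cycle interval runs from one inhalation
peak to the next and contains the full falling limb of peak `i` plus the
rising limb toward peak `i+1`; for a baseline-anchored waveform its
peak-to-peak excursion is therefore `max(a_i, ~a_{i+1})` (the rising
limb reaches almost the full next peak). The standard deviation of these
interval maxima is noticeably smaller than the SD of the drawn heights
(about 0.83× for the default settings). Any analysis that measures
per-cycle peak-to-peak amplitudes — this package's, or a clinical
system's — estimates the realized quantity, so `true_amp_sd` is defined
as the sample SD of `cycle_amplitudes`, and recovery is validated
against it. `true_mean_period_s` is the median inter-peak interval,
matching the robust estimator used by the analysis side.

## 2. Preprocessing

Three steps, in order, each recorded in a provenance structure:

1. **Beam-on windowing** (only if the curve carries per-sample beam-on
   flags): restrict to the inclusive span from the first to the last
   flagged sample.
2. **Linear drift removal**: subtract the ordinary-least-squares line
   (slope only; the mean level is preserved). OLS commutes with affine
   amplitude maps, so this step does not break affine invariance.
3. **Min-max normalization** to `[0, 1]`. The recorded `scale` (raw
   range) and `offset` allow any normalized quantity to be mapped back
   to raw units, e.g. `amp_p2p_sd_raw = amp_p2p_sd * scale`.

Together these make all downstream metrics exactly invariant under
`x -> a*x + b` with `a > 0`, and insensitive (sub-2% shift) to linear
drift up to 0.05 a.u./s.

## 3. Cycle analysis

- **Inhalation peaks**: local maxima with prominence ≥ 0.2 (on the
  normalized trace) and separation ≥ 1.0 s; when candidates conflict,
  higher peaks win.
- **Cycles**: half-open intervals `[p_i, p_{i+1})` between consecutive
  peaks; per-cycle peak-to-peak amplitude is max − min within the
  interval; the cycle-length estimate is the *median* inter-peak
  interval (robust to pauses).
- **Phase binning**: each sample in a cycle gets phase fraction
  `f = (t − p_i) / (p_{i+1} − p_i)` and bin `min(floor(f · n), n − 1)`
  with `n = 10` phases by default; samples before the first or after the
  last peak are unassigned.

## 4. Irregularity metrics, selection, matching

- **Amplitude variability** `amp_p2p_sd`: sample SD (n−1 denominator) of
  the per-cycle peak-to-peak amplitudes of the preprocessed curve — a
  dimensionless fraction of the total respiratory excursion.
- **Breathing pauses**: inter-peak gaps ≥ 1.5× the median cycle length.
  The reported duration is the full inter-peak gap, so an inserted hold
  of `d` seconds appears as a gap of roughly `d` plus one cycle.
- **Selection**: the most irregular curves of a cohort are the top 15 by
  `amp_p2p_sd` plus, among the remainder, the top 10 by longest pause —
  a disjoint 15+10 split (ties break by curve id).
- **Matching**: a second cohort is matched to the selection by greedy
  nearest-neighbour search without replacement on the respective
  statistic, processing reference curves in descending statistic order.

## 5. Acquisition simulation

Both protocols are modeled on a 1-D couch axis. The simulators capture
*timing and phase consistency*, not reconstruction physics: artifact
genesis in 4D CT is fundamentally about which breathing states are
available at which couch position, which a 1-D timing model represents
faithfully.

### Spiral (retrospectively gated)

The couch moves continuously at `pitch × collimation / rotation_time`
(default 0.09 × 19.2 mm / 0.5 s ≈ 3.46 mm/s). Each slice station —
stations are collimation-width bins over the field of view — is inside
the beam for a fixed window of `rotation_time / pitch` ≈ 5.56 s while
the aperture passes over it. The scan starts at the first phase-assigned
sample and irradiates continuously (duty cycle 1 by construction). For
each (station × phase bin) cell the simulator selects one sample from
the station's window; a cell with no sample of that phase in the window
is *missing*.

With regular ~4 s breathing the 5.56 s window always contains a full
cycle and every cell is filled. An irregular cycle or a pause inside the
window starves phase bins (missing cells) or forces the cell to be
filled from a non-representative cycle (amplitude mismatch across
stations).

### Sequence / breathing-adapted (i4DCT-style)

Reference cycle statistics (median period, median peak-to-peak
amplitude) are learned from the first 3 cycles. The couch then steps
through stations spaced one couch increment apart (default
0.9 × 38.4 mm = 34.56 mm). At each station the beam turns on at the next
confirmed cycle start and stays on until a completed *representative*
cycle plus one rotation time has been recorded, or a 30 s maximum dwell
is reached; between stations the couch move costs 0.8 s of dead time.
Gating decisions are causal: a peak at time `p` is usable one sample
after `p`.

A completed cycle is representative when all of the following lie
within tolerance of the reference (period ±35%, amplitudes ±25%):

1. its duration,
2. its peak-to-peak excursion,
3. its *opening* peak height above the cycle minimum, and
4. its *closing* peak height above the cycle minimum.

Checks 3 and 4 exist because a 10-phase reconstruction uses the falling
limb below the opening peak for the early bins and the rising limb into
the closing peak for the late bins: a cycle with a representative
excursion but an anomalous bounding peak would still stitch an
inconsistent motion state into the first or last phase bins of that
station.

Reconstruction at a station uses the accepted cycle's samples; if a
phase bin happens to be empty within that cycle the rest of the dwell is
used as a fallback. If no cycle is accepted before the maximum dwell,
the station is flagged *incomplete* and the best-scoring completed cycle
in the dwell (smallest maximum normalized deviation from the reference)
is used best-effort — mirroring a scanner that must produce an image
even when gating times out.

### Artifact proxies

- `interpolation_count`: number of missing (station × phase) cells —
  missing phase data would have to be interpolated in time.
- `double_structure_score`: mean absolute amplitude difference between
  the samples selected at adjacent stations for the same phase,
  normalized by the median cycle peak-to-peak amplitude — adjacent
  stations reconstructed from inconsistent motion states are what shows
  up as duplicated anatomy.

Within each station window/cycle, the sample whose phase fraction is
closest to the bin center is selected (ties break by time). Selecting by
time alone would land at varying within-bin offsets at adjacent stations
and register spurious mismatch even for perfectly periodic breathing.

### Default parameters

| Parameter | Spiral | Sequence | Unit |
|---|---|---|---|
| rotation time | 0.5 | 0.5 | s |
| pitch | 0.09 | — | – |
| collimation | 16 × 1.2 = 19.2 | 64 × 0.6 = 38.4 | mm |
| couch speed / increment | 3.456 mm/s | 34.56 mm/step | |
| illumination window | 5.556 | adaptive | s |
| phases | 10 | 10 | – |
| amplitude tolerance | — | ±25 | % |
| period tolerance | — | ±35 | % |
| learning cycles | — | 3 | – |
| couch dead time | — | 0.8 | s |
| maximum dwell | — | 30 | s |
| field of view | 150 | 150 | mm |

## 6. Rank statistics

Implemented from first principles so the exact small-sample behaviour is
fully specified (library routines are used only as test oracles):

- **Mann-Whitney U**: `U = #{(i,j): x_i > y_j} + ½·ties`, computed via
  pooled mid-ranks. For pooled `n ≤ 12` without ties the two-sided
  p-value is obtained by full enumeration of all `C(n, n_x)` group
  labelings; otherwise a normal approximation with tie-corrected
  variance and 0.5 continuity correction is used.
- **Spearman's rho**: Pearson correlation of mid-ranks; undefined (and
  rejected) for constant inputs.
- **Score summaries** for 1–5 ordinal grades: fractions ≥ 4 and ≤ 2,
  mean, per-score incidence.

## 7. Study driver and determinism

`run_study` generates two synthetic cohorts (default 60 curves each,
240 s at 25 Hz, parameters drawn per curve from configurable ranges),
computes per-curve metrics, selects the 15+10 most irregular curves of
cohort A, matches cohort B to them, simulates both protocols on every
curve of every matched pair, and writes JSON outputs plus a run log.

Per-curve seeds derive from the master seed via
`numpy.random.SeedSequence` with spawn key `(cohort_index, curve_index)`
(masked to 31 bits), so results are byte-deterministic, independent of
execution order, and stable under cohort extension. All JSON is written
with sorted keys and shortest round-trip float formatting.

## 8. Limitations

- The generator's cos-power model omits cardiac interference, slow
  baseline oscillations, irregular waveform shapes and signal dropouts;
  its pauses are pure end-exhale holds at exactly baseline level.
- The acquisition models are 1-D timing surrogates: no projection
  geometry, no reconstruction, no dose model; the artifact proxies are
  monotone indicators of artifact *risk*, not image-quality scores.
- The sequence gating surrogate is a plausible reconstruction of a
  representative-cycle criterion (period + three amplitude checks), not
  a vendor algorithm.
- Human image-quality grading and learned artifact detectors are out of
  scope; `score_summary` only processes externally supplied grades.
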