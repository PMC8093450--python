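# Methods

This note documents the models, parameter choices, and numerical conventions
behind `cogload`, and what the synthetic-data tests do and do not establish
about real recordings.

## Recording model and preprocessing

All recordings are CSV time series with a strictly increasing `t_s` column
(seconds). Invalid samples (blinks, track loss, NaN) are flagged, never
dropped, so each metric decides its own gap policy. Segmentation by event
logs uses closed intervals; samples on a segment boundary belong to the
segment.

Resampling to a uniform grid (required before any FFT/PSD) is linear
interpolation over valid samples; grid points whose nearest original sample
was invalid stay flagged, so gap structure survives resampling.

**Outer fencing.** Outliers are values outside [Q1 − 3·IQR, Q3 + 3·IQR].
Quartiles use linear interpolation of the empirical CDF (type 7, numpy's
default); the multiplier 3 is the standard "outer" fence (1.5 would be the
inner fence). The pipeline applies the fence per metric within each
condition, across participants — the most conservative grouping that still
leaves ≥ 4 values per group at the default study size; the grouping is a
parameter. The filter is idempotent on clean data and requires at least 4
finite values.

## Pupil metrics

Epochs with < 50% valid samples are rejected. Invalid runs ≤ 500 ms (blinks)
are bridged by linear interpolation; longer runs split the epoch, and
sub-epoch metrics are re-aggregated weighted by duration.

**L1NS** operates on the mean-subtracted diameter with an epoch-length FFT,
single-sided 2/N amplitude scaling (DC and Nyquist unscaled), summing bins
with 1 Hz ≤ f ≤ 5 Hz inclusive. A unit-amplitude in-band sinusoid therefore
scores its amplitude exactly (at integer cycle counts). Choices made where
the convention was open: amplitude (not power) summation — a power variant
is available via `mode="power"`; no taper window by default (an optional
Hann taper, amplitude-normalised, suppresses spectral leakage from
non-integer-cycle drift at the cost of in-band scalloping). Mean
subtraction removes the dominant DC term before transforming. Epochs must
be ≥ 2 s (two cycles of the lowest analysed frequency).

With the rectangular default, a slow drift component leaks a small constant
offset into the band (the 1/Δf sidelobe sum does not vanish with epoch
length); it is condition-independent and cancels in paired comparisons,
which is what the pipeline relies on.

**STDP** is the sample standard deviation (n − 1). **LPF** is the mean
absolute value of the zero-phase (forward–backward) 4th-order Butterworth
low-pass at 4 Hz of the mean-subtracted diameter. Filter family, order,
cutoff, and the scalar reduction are unspecified in the source methods;
these defaults keep the metric inside the L1NS band and are all keyword
parameters. All three metrics are translation invariant and non-negative;
the left and right eyes are kept separate throughout (no binocular
averaging).

## Gaze metrics

**I-VT.** Angular velocity is the central difference of gaze position over
valid neighbours (one-sided at edges). Samples with velocity ≥ 30°/s are
saccades, the rest fixations; invalid samples break runs; fixations shorter
than 60 ms are discarded (a common default; the threshold is a parameter).
Fixation centroids are member-sample means.

**NNI.** d_NN is the mean nearest-neighbour Euclidean distance over the
point set (KD-tree); d_MRD = 0.5·√(area/N) with area the bounding rectangle
of the points (Clark–Evans expected distance, no edge correction). The
default point set is fixation centroids; raw gaze samples can be passed
directly. Degenerate (zero-area) sets score 0 with a warning. The index is
scale invariant.

**Saccadic intrusions.** The detector scans for excursions of the
horizontal channel away from a local baseline (median of the preceding
100 ms, required to be *stable*: peak-to-peak ≤ 0.2° over the window). An
event must leave the 0.4° return neighbourhood by a 0.1° hysteresis margin
and return within 60–870 ms; excursions above 2.5° are ordinary saccades
and are rejected, and a candidate that settles at a stable level away from
the baseline (peak-to-peak ≤ 0.2° over 200 ms) is abandoned immediately as
a gaze shift — without this, every saccade would blind the detector for the
full 870 ms window, and with only the short 100 ms stability window the
apex of a slow pulse can masquerade as a settled level. Onset and return
are refined to the flanking local minima of |deviation|, so a clean
triangular 1° pulse of 200 ms yields amplitude 1°, duration 200 ms, and
velocity 2·1/0.2 = 10°/s — the out-and-back path over elapsed time, which
is the velocity convention reported (peak velocity is not).

## EEG metrics

Bands: theta 4–8, alpha 8–13, low-beta 13–21, high-beta 21–30, gamma
31–100 Hz. PSDs are Welch estimates with 2 s Hann windows and 50% overlap
(0.5 Hz resolution, enough to resolve the 4 Hz theta edge); band power is
the trapezoidal integral over the band, clipped at Nyquist with a warning
(relevant for gamma at 128 Hz sampling; gamma is excluded from default
summaries). Recordings are summarised per band as the median over channels
× sliding 10 s epochs, pooled — one median per band per recording, matching
a design that reports one value per condition. Epochs with > 20% invalid
samples are skipped; isolated invalid samples are bridged by interpolation.
No ocular-artifact regression or ICA is applied.

## Inceptor and flight metrics

Duty cycle marks interval i active when |δ_i − δ_{i−1}|/(t_i − t_{i−1}) ≥
0.5 mm/s (noise threshold) or |δ_i| ≥ δ_max (80 mm full scale; both
parameters). The default is time-weighted, DC = 100·Σx_i Δt_i/(t_n − t_1),
a true percentage of elapsed time: idle traces score exactly 0 and fully
active traces exactly 100. A `strict_printed` mode reproduces the
unweighted per-sample count over (t_n − t_2) for comparison; the two agree
up to a factor ≈ 1 under uniform dense sampling. The rate comparison uses
the absolute value — a signed rate would count any leftward motion as
active. Aggressiveness is the mean squared deflection rate over intervals,
offset invariant and quadratic in scale.

%RMSE normalises the RMSE about the task reference — altitude-band midpoint
(4500 ft for the 4000–5000 ft band) or trim airspeed (120 kt) — by that
reference; both references are parameters.

## Statistical harness

Implemented from closed forms (their small-sample oracles are exact) and
cross-checked against scipy/pingouin in the test suite: Friedman χ² with
average within-row ranks and the standard tie correction (χ²(2) = 8 for
four concordant rows over three conditions; an all-tied table scores 0);
Wilcoxon signed-rank with zero differences dropped, W = min(W+, W−), exact
two-sided p by enumeration for n ≤ 25 without ties, otherwise the normal
approximation with tie and continuity corrections (both W and Z are
reported — published "Z" values are sometimes W statistics, so the report
never leaves the reader guessing); Spearman ρ by the 1 − 6Σd²/(n³−n)
formula without ties and rank-Pearson with ties, p via the t approximation;
RM one-way ANOVA with subject blocking, partial η² = SS_cond/(SS_cond +
SS_error), and an explicit degenerate flag when SS_error = 0. The
Anderson–Darling test uses the estimated-parameters case with the
A²(1 + 0.75/n + 2.25/n²) modification and the D'Agostino–Stephens p
approximation.

The pipeline's gate routes each metric at α = 0.05 on the pooled
within-condition residuals: non-normal → Friedman + pairwise Wilcoxon,
normal → RM-ANOVA + paired t. Raw p-values are reported (no
multiple-testing adjustment by default, matching the source analysis; Holm
is available as an option). Pairwise cells are flagged at 0.1/0.05/0.01.
Conformance pools all participant × condition recordings (36 points at the
default design) — per-participant partial correlation is an option, not the
default.

## Synthetic studies

The generator emulates a 12-participant × 3-condition within-subject design
(C1 baseline flight, C2 altitude-band constraint, C3 added secondary task;
latent workloads 0.25/0.45/0.90, chosen so the C1–C2 contrast is weak and
the contrasts against C3 strong), 240 s per recording, gaze/pupil at 100 Hz
(the eye-tracker rate), EEG at 128 Hz, inceptor at 50 Hz, flight state at
10 Hz. Every workload pathway is a gain in an explicit effect map; setting
all gains to zero produces the exact null (identical condition
distributions), which the calibration tests exploit. By default the SI-rate
and SI-velocity gains are zero — the source studies found those metrics
insensitive — so the pipeline must *not* flag them.

Signal models are intentionally minimal so each metric's driving property
is independently tunable:

- **Pupil**: 3 mm baseline (per-participant offset, SD 0.25 mm) + <0.2 Hz
  drift (0.15 mm) + a 4-sinusoid 1–5 Hz bank with total amplitude
  0.08·(1 + 1.5·w) mm + white noise, eyes sharing the deterministic parts
  and most noise (r ≈ 0.9); Poisson blinks (0.05/s, 100–300 ms) as invalid
  runs.
- **Gaze**: fixation targets from a fixed four-point scan layout with
  per-cluster spread 0.4·(1 + 2.5·w)° and inter-cluster jump probability
  0.15 + 0.6·w; dwells uniform 200–800 ms; fixed 20 ms saccade transitions.
  Two constraints keep the null metrics null: every jump is ≥ 1.5° (so even
  boundary samples exceed the I-VT threshold at any workload — otherwise
  small jumps merge fixations more often at low workload) and no fixation
  returns horizontally to within 0.7° of the one before last (otherwise
  quick there-and-back scans satisfy the SI definition at a
  workload-dependent rate). Triangular SI pulses (0.6–1.2°, 150–400 ms) are
  planted inside long fixations at 0.15·(1 + g_SI·w)/s with ≥ 1 s
  separation.
- **EEG**: 1/f background + per-band 5-sinusoid banks with amplitudes
  (theta 4, alpha 5, low-beta 3, high-beta 2 µV) scaled by (1 + g_band·w),
  g = 0.8/0.6/0.8/0.7; five channels share 70% of every component.
- **Inceptor/flight**: alternating idle holds and active bouts
  (exponential durations, mean 2 s active) with active fraction
  0.2·(1 + 1.8·w) capped at 0.95; active bouts are piecewise ramps at
  1.5–8 mm/s, reflecting off 70% of full scale. Altitude and airspeed are
  AR(1) errors about their targets with stationary SDs 60 ft and 4 kt
  scaled by (1 + 1.5·w), time constants 20 s and 10 s.
- **N-back**: digits 1–9 every 2 s; a scripted responder hits targets with
  probability p_hit and false-alarms with p_fa; tallies follow the
  (correct + avoid)/total accuracy definition exactly.

All randomness flows through numpy's PCG64 with `SeedSequence`-derived
per-recording streams, so a study is byte-identical given its seed,
independent of generation order and platform.

**What passing tests show — and do not.** The synthetic signals verify the
metric implementations (oracle values, scaling laws, recovery of planted
structure) and the statistical machinery (size, power, flag pattern). They
do not establish that the metrics separate workload in real recordings:
real pupil data has light-reflex dynamics and foreshortening, real EEG is
nonstationary with ocular artifacts, real scanning is task-structured, and
real inceptor activity couples to the aircraft dynamics. None of those are
modelled, deliberately.

## Problem sizes and numerical notes

The test suite and the acceptance script use 120 s recordings for the
end-to-end study (and 2000 replicates for null calibration, 100 × 1000
points for the spatial-randomness baseline); the analysis drivers default
to the full 240 s. Exact oracle assertions use closed-interval band edges,
so sinusoid tests place tones on exact FFT bins; stochastic assertions fix
their seeds and state their tolerances inline. Degenerate inputs (constant
vectors, zero-area point sets, all-tied tables, SS_error = 0) return
explicit flagged results or typed errors — nothing silently produces NaN
except the documented missing value of `median_si_velocity` when no
intrusions are detected.

## Known limitations

- The SI detector's settled-level abort can miss intrusions with a flat
  plateau longer than 200 ms (square-wave-jerk-like events); the generator
  plants triangular pulses, and plateau events would need a different
  abort criterion.
- Band-power additivity holds only up to trapezoidal integration error at
  shared band edges.
- The Wilcoxon exact path is disabled under ties in |differences|; tied
  data uses the corrected normal approximation even at small n.
- `extract_metrics` isolates failures per modality, not per metric: a gaze
  file that parses but yields no valid samples drops all gaze/pupil
  metrics for that cell.
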