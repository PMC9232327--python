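# Methods

## Analysis model

The unit of analysis is a metronome-paced *trial*: one athlete performs a
fixed arm-lifting combination at a constant tempo (default 120 beats/min), so
each beat lasts `60/tempo` s and a combination of `n` beats spans
`n · 60/tempo` s.  The hand marker is treated as the endpoint of the arm; all
kinematic quantities derive from its sampled 3D position.

**Coordinate convention.** X mediolateral, Y anteroposterior, Z vertical, so
XY is the horizontal (transverse) plane, XZ the frontal plane and YZ the
sagittal plane.

**Amplitude.** Action track length is the cumulative Euclidean length of the
sampled path.  Plane-projected lengths apply the same sum to the two retained
coordinates, which by the triangle inequality never exceeds the 3D length.
Relative track length divides by subject height per subject *before* group
averaging (a ratio of group means is not the same quantity and is not used).
Left- and right-hand summaries are combined by arithmetic mean.

**Speed and braking.** Velocity is estimated by central finite differences
(one-sided at the series ends), with no smoothing by default; a centered
moving-average position smoother is available in the run config.  At 30 Hz
with millimeter-level coordinate noise the unsmoothed estimator is adequate
and transparent.  Within each beat the braking interval runs from the frame of
maximum speed to the earlier of the first post-peak frame at or below the
zero-speed threshold (default 1e-3 m/s) and the beat's final frame; it yields
`Δv = v_end − v_peak` and `ā = Δv/Δt`.  Beats whose speed peak falls on the
final frame have no deceleration phase (`Δt = 0` would make `ā` unbounded);
they are logged and excluded from summaries.  Hand averaging of braking
metrics is the arithmetic mean of per-hand `Δv` and `ā` per beat.

**EMG metrics.** RMS is `√((1/N)Σxᵢ²)`; iEMG integrates the rectified signal
by a left Riemann sum (`Σ|xᵢ|/rate`, mV·s), so windows that partition a trial
sum exactly to the whole-trial value; a trapezoid rule is available and
differs negligibly at 1000 Hz.  Beat windows map boundary times to samples by
nearest rounding and are half-open.  An optional zero-phase 20–450 Hz
band-pass (4th-order Butterworth, applied forward-backward) precedes the
metrics when enabled; it is off by default because the synthetic carrier is
already band-limited.

**MVIC standardization.** The reference for each channel is the highest RMS
over a sliding 1-s window of that channel's MVIC trial — the windowed maximum
is the common convention and is robust to effort onset/offset.  Standardized
RMS is `100 · rms / reference` (values above 100% are legal).  iEMG is
standardized against the MVIC iEMG over a window of *equal duration*
(`reference_mean_abs · T`), which makes the percentage comparable across
window lengths; the reference mean rectified amplitude is stored alongside the
reference RMS for this purpose.

**Statistics.** Group summaries use the sample SD (n−1).  "Independent
samples t-test" defaults to the pooled-variance Student test (the usual
reading in SPSS-era sports-science reporting) with Welch selectable.
Significance is flagged at P < 0.05 and P < 0.01.  When both groups are
constant with equal means the statistic is undefined and is reported as
non-significant with a warning.  Pearson correlations carry a verbal grade
from configurable |r| bands (defaults: none < 0.1 ≤ weak < 0.3 ≤ moderate
≤ 0.7 < strong).  No multiple-testing correction is applied by default,
matching per-metric reporting conventions; a Holm adjustment helper is
provided but off.

## Synthetic cohort generator

The generator's defaults *are* the emulated study conditions; they are fixed
once here and not tuned per analysis.

| parameter | default | meaning |
|---|---|---|
| n_group_a / n_group_b | 4 / 11 | the graded/ungraded split of a 15-athlete squad |
| tempo, frame_rate, emg_rate | 120 bpm, 30 Hz, 1000 Hz | metronome and recording rates |
| height | Normal(1.77, 0.09²) m, truncated > 0 | cohort stature distribution |
| amplitude_scale | A 1.15, B 1.00 | group-A movement-amplitude surplus |
| braking_sharpness | A 1.2, B 1.0 | time-warp exponent; larger = later speed peak, steeper braking |
| subject_amplitude_sd | 0.07 | between-trial multiplicative amplitude CV (matches a ~7% SD/mean ratio typical of such cohorts) |
| coord_noise_sd | 0.003 m | additive marker noise |
| muscle weights | A latissimus-dominant; B left-triceps / right-biceps-dominant | group force profiles |
| side_asymmetry | 1.3 | right-over-left envelope factor (muscle-keyed weights only) |
| emg_gain_mv | 0.1 mV per m/s | envelope drive gain |
| emg_noise_sd | 0.01 mV | additive channel noise |
| mvic_drive | 8.0 (m/s-equivalent) | MVIC envelope; chosen above the largest possible task envelope so standardized values stay bounded below 100% |

**Movement model.** Each beat is a straight-line point-to-point move through
a canonical via-point geometry (shoulder height 1.45 m, half-width 0.20 m,
arm 0.60 m) following the minimum-jerk profile `s(τ) = 10τ³ − 15τ⁴ + 6τ⁵`,
which starts and ends at rest and has peak speed `15·d/(8·T)`.  Group braking
differences warp time as `τ → τ^k` (rest boundary conditions preserved).  The
side lift sits at 70° azimuth (slightly forward of pure lateral) and the
chest cross reaches across the midline at shoulder height; the 4-beat
combination starts from the side-down pose so it forms a closed loop.  These
choices were made at construction time so that the 8-beat combination moves
most in the sagittal plane and the 4-beat combination most in the horizontal
plane — the qualitative structure the analysis is designed to resolve — and
give trial path lengths of roughly 4–8 m, the plausible scale for sequences of
~0.9 m arm sweeps.

**EMG model.** Each channel is `gain · weight · side_factor · speed(t)` times
a band-limited (20–450 Hz) zero-mean unit-RMS Gaussian carrier, plus additive
Gaussian noise.  Speed-proportional envelopes encode the assumption that
larger/faster movements recruit proportionally more activity, which induces a
positive within-group correlation between track length and standardized EMG.
Weight maps may be keyed by muscle (asymmetry factor applied to the right
side) or by `side_muscle` (used verbatim), which is how group B's left-triceps
/ right-biceps dominance is expressed.

**What the generator does not emulate.** No joint kinematics or dynamics, no
motor-unit action-potential structure (the carrier is Gaussian noise), no
electrode crosstalk, no fatigue, no within-beat technique variation beyond the
minimum-jerk family, and no amplitude-independent EMG variability — the last
means within-group track-length/EMG correlations in synthetic cohorts are
near 1, far stronger than real athletes would show.  Passing recovery tests
therefore demonstrates that the pipeline resolves effects of the configured
kind and size under clean conditions, not that it would on any particular real
data set.

## Reproducibility and numerical choices

* All randomness flows from a single integer seed through spawned
  `numpy.random` seed sequences (one stream per subject × stage), so a config
  reproduces its cohort bit-for-bit and motion data are unchanged whether or
  not EMG is generated.
* Beat boundaries are rounded multiples of `(60/tempo)·frame_rate`; the frame
  count must match the tempo/beat-count product within one frame, else
  segmentation fails loudly.
* CSV output uses `%.12g` floats and JSON uses sorted keys, making every
  artifact byte-stable; the report renders at 3 decimals.
* Degenerate inputs fail with typed errors (`InvalidArgumentError`,
  `InsufficientDataError`, `ConfigurationError`, `SegmentationError`,
  `UndefinedCorrelationError`); the analysis stage isolates failures per
  subject and stage, records them in the run manifest and continues.

## Problem sizes

Recovery sweeps (in the test suite and `scripts/acceptance.py`) use 100 seeded
cohorts of the default 15-subject study per condition: amplitude ordering at a
1.15 scale ratio, false-positive rate at ratio 1.0 against the binomial 95%
band around the nominal 5%, and latissimus/right-side dominance with the
default weight profiles.  Oracle suites use 200 random 50-point trajectories.

## Known limitations

* The via-point geometry is canonical, not subject-specific; stature affects
  only the relative-length denominator, not the generated path.
* Standardized synthetic EMG stays below 100% MVIC by construction, although
  the standardization operation itself permits larger values (real athletes
  can exceed their isometric reference during dynamic tasks).
* The braking-sharpness warp changes when the speed peak occurs but not the
  minimum-jerk family itself; real deceleration profiles are freer.
* Group assignment is an input; nothing in the package scores technique
  quality.
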