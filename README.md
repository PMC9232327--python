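# armbiomech

Biomechanical analysis of metronome-paced arm movements from 3D hand
trajectories and surface EMG, built for two-group comparisons of competitive
martial-arts (Taijiquan-style) arm manipulation technique.

Given per-hand 3D coordinate time series segmented into metronome beats and
synchronized multichannel sEMG, the package computes:

* **Movement amplitude** — the action track length
  `L = Σₙ √((xₙ₊₁−xₙ)² + (yₙ₊₁−yₙ)² + (zₙ₊₁−zₙ)²)`, its projections onto the
  horizontal (XY), frontal (XZ) and sagittal (YZ) anatomical planes, and the
  height-normalized *relative track length* `L / height`.
* **Braking** — per beat, the speed change from the within-beat peak to the end
  of the deceleration phase, `Δv = v_end − v_peak ≤ 0`, and the mean
  acceleration `ā = Δv/Δt`; speed is obtained from central finite differences
  of the hand position.
* **Muscle activity** — per-channel RMS `√((1/N)Σxᵢ²)` and integrated EMG
  `∫|x(t)|dt` over beat windows and whole trials, standardized to a maximum
  voluntary isometric contraction (MVIC) reference taken as 100%.
* **Group statistics** — mean ± SD per group with signed A−B differences,
  two-sided independent-samples t-tests (pooled Student by default, Welch
  selectable) flagged at P < 0.05 / P < 0.01, and Pearson correlations among
  track length, standardized RMS and iEMG, graded by |r| bands.

Because studies of this kind rarely deposit raw capture data, the package
includes a first-class seeded **synthetic cohort generator**: minimum-jerk
beat-to-beat hand movements through a canonical via-point geometry (two fixed
combinations: an 8-beat front/up/side/down lifting sequence and a 4-beat
chest-cross + side-lift sequence at 120 beats/min, 30 Hz), and 8-channel
1000 Hz EMG whose envelope follows the hand speed with group-specific muscle
weights and a right-over-left asymmetry.

## Worked example

`python examples/group_comparison.py` generates the default cohort
(4 group-A + 11 group-B athletes, seed 7) and compares hand-averaged 3D track
lengths for the 8-beat combination:

```
group A: 7.866 ± 0.651 m (n=4)
group B: 6.765 ± 0.370 m (n=11)
difference (A−B): 1.101 m, t = 4.183, p = 0.0011 *
group B track length vs standardized RMS: r = 0.995 (p = 0.0000, strong)
```

Group A's larger mean reflects its configured 15% amplitude surplus; the
positive within-group correlation arises because the EMG envelope is driven by
hand speed, so larger movements recruit proportionally more activity.  The
other examples cover cohort file generation (`simulate_cohort.py`), per-plane
amplitude (`track_length.py`), per-beat braking (`braking.py`) and
MVIC-standardized EMG (`emg_metrics.py`).

## Command line

A thin CLI wraps the same pipeline:

```
armbiomech simulate --config cfg.yaml --out cohort/
armbiomech analyze  --config cfg.yaml --in cohort/ --out metrics/
armbiomech report   --in metrics/
```

`simulate` writes per-subject trajectory/EMG/MVIC CSVs plus a JSON manifest;
`analyze` writes per-subject metrics CSVs and group-level stats CSVs;
`report` renders a deterministic markdown report (3-plane amplitude tables,
per-beat braking tables, per-channel standardized EMG, correlation panel, with
`*`/`**` significance stars).  All three are reproducible byte-for-byte from
the seed.

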