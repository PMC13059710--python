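# chemosignal

Quantitative pipelines for measuring bacterial chemotaxis signaling, built
around the three assays used to characterize *Escherichia coli*'s
Aer-mediated avoidance of reactive oxygen species (ROS): the tethered-bead
flagellar-motor assay, three-cube E-FRET measurement of CheA kinase
activity, and defocused diffraction-ring 3D tracking of cells inside swarm
colonies. Each analysis stage is paired with a ground-truthed synthetic-data
generator, so every estimator can be validated end-to-end without raw
microscopy data.

## Who this is for

Researchers analyzing single-motor switching statistics, ratiometric FRET
time series, or defocused-imaging z-localization data — and anyone who
wants a simulated testbed in which the true motor state, kinase activity,
or cell height is known exactly.

## The statistics at the core

**Motor rotation.** A bead on a flagellar stub orbits with the motor;
clockwise (CW) rotation is positive by convention. From the per-frame
direction labels,

    CW bias = CW_time / (CW_time + CCW_time)

(pauses excluded), smoothed with a 30-s running average for long
recordings; a reversal is one CW↔CCW switching event, reported per minute.
The synthetic motor is a two-state continuous-time Markov process with
rates k₁ (CCW→CW) and k₂ (CW→CCW), for which the stationary CW bias is
k₁/(k₁+k₂) and the reversal rate is 2k₁k₂/(k₁+k₂) — the exact jump-chain
path serves as the oracle for every estimator check.

**E-FRET.** With IDD (donor emission, donor excitation), IDA (acceptor
emission, donor excitation) and IAA (acceptor emission, acceptor
excitation), the apparent FRET efficiency is

    E_app = (IDA − a·IAA − d·IDD) / (IDA − a·IAA + (G − d)·IDD)

where a, d are bleed-through constants and G the gauge factor.
Photobleaching is corrected first by fitting IDD and IAA to bi-exponential
decays; kinase activity is E_app rescaled per cell between the means of
saturating-stimulus windows, so 0–1 spans kinase-OFF to kinase-ON.

**z-tracking.** An out-of-focus cell's diffraction-ring diameter grows
linearly with height: z = (diameter − d₀)/slope. Ring diameters are
estimated from images by radial intensity profiling with sub-pixel peak
interpolation; conditions are compared with a paired Student's t-test on
per-replicate mean heights.

## Worked example

```bash
python analysis/01_simulate_cohorts.py   # generate all cohorts (scratch/sim)
python analysis/02_motor_response.py     # bead-assay pre/post comparison
python analysis/03_fret_pipeline.py      # bleach -> E-FRET -> activity
python analysis/04_swarm_ztrack.py       # colony z-distributions
```

Output of the motor comparison (20 motors per cohort, 60 s before and
after the stimulus):

```
wt_baseline: pre 40.6 rev/min, post 39.1 rev/min, p = 0.56
wt_peroxide: pre 39.8 rev/min, post 55.8 rev/min, p = 2.3e-08
```

The baseline cohort shows no pre/post change (p = 0.56), while the
peroxide preset jumps from its ~39 reversals/min baseline toward the
repellent level (~65 rev/min at the step, averaging ~56 over the adapting
60-s window) — a strongly significant repellent response. The FRET
pipeline recovers the simulated kinase activity with RMSE 0.010 and a
mean adaptation time of ~55 s, and the swarm analysis finds
surface-avoiding cells at mean z ≈ 106 µm versus ≈ 76 µm for uniformly
distributed cells, with zero bottom-layer occupancy for the avoiders
(paired t, p < 10⁻⁵).

The same pipelines are scriptable through the CLI, e.g.:

```bash
chemosignal simulate motor --preset wt_peroxide --n-motors 5 --seed 1 --out sim/
chemosignal motor --in sim/motor_000.csv --stimulus-time 60 --out summary.json
```

## Layout

- `src/chemosignal/` — the library: `synthetic` (generators), `motor`,
  `fret`, `ztrack` (analysis), `io` (formats/config/pipeline), `cli`,
  `presets` (named experimental conditions).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — models, parameter choices, numerical details and
  limitations.
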