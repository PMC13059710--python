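# Methods

This note documents the models behind each pipeline, the default
parameters and why they were chosen, what the synthetic data does and
does not emulate, and the numerical choices that matter.

## Motor switching model and bead-assay analysis

The flagellar motor is modeled as a two-state continuous-time Markov
process with transition rates k₁ (CCW→CW) and k₂ (CW→CCW), sampled
exactly through its jump chain (exponential dwell times; piecewise-
constant rate windows are handled by advancing to the window boundary
and resampling, valid by memorylessness). Stationary observables are
CW bias β = k₁/(k₁+k₂) and reversal rate R = 2k₁k₂/(k₁+k₂). Presets
encode only observable statistics — baseline 39.07 reversals/min,
repellent 64.53 reversals/min — inverted through those relations.
Baseline CW bias is set to 0.20 (0.35 under repellent), typical
bead-assay values for a predominantly-CCW wild-type motor; no numeric
bias is reported for these conditions, so these are modeling choices.
Stimulus responses are step changes in the rates that relax back to
baseline exponentially with a 60-s time constant (adaptation on the
~1-min scale), discretized into 1-s piecewise-constant segments.
Optional pauses are inserted at switches with a configurable
probability (default 0) and fixed dwell; nothing mechanistic is implied.

The bead is placed on a circular orbit (default radius 0.25 µm) whose
angle integrates ±2π·speed per second by state, plus Gaussian position
noise (default SD 0.01 µm). Rotation speed defaults to 10 Hz in
simulations; reversal statistics are independent of speed and frame
rate once the rotation is resolved (phase step < π per frame), so
estimator-recovery runs use 100–250 frames/s rather than the assay's
native 1000 frames/s to keep run times practical — a problem-size
choice, not a model statement. The direction-detection chain is:
running-centroid orbit center (1-s window, truncated at the edges to
avoid padding bias), unwrapped atan2 angle, central-difference angular
velocity, sign convention CW = positive (flag available for image
y-axis-down data). Classification uses a 2-Hz pause threshold and a
10-ms minimum dwell; shorter runs are merged into the longer flanking
run. Reversal counting bridges pauses: CCW→PAUSE→CW counts once,
CCW→PAUSE→CCW counts zero. The discretization makes the estimator
blind to dwells shorter than the debounce window, an ~0.5% undercount
at baseline rates — visible only against the exact jump-chain oracle
and well inside sampling error at the cohort sizes used.

The 30-s running average of CW bias is centered, with truncated
windows at the edges; recordings shorter than the window fall back to
a single whole-trace value with a warning. Pre/post comparisons use
the equal-variance two-sample Student's t-test by default (Welch
available); groups whose values are identical constants return
t = 0, p = 1 rather than NaN.

## FRET forward model and E-FRET analysis

Kinase activity is phenomenological: baseline 0.3, stimulus step to
0.9 relaxing back with adaptation time constant τ = 20 s (so the
trajectory re-enters a ±2% band of baseline within roughly a minute),
removal undershoot 0.2 recovering with the same τ. Saturating
calibration windows at the start (kinase-OFF) and end (kinase-ON) of
the default 240-s protocol pin activity to 0 and 1. FRET efficiency is
an affine map of activity between e_min = 0.10 and e_max = 0.45.
Channels are built so the E-FRET equation is an exact identity at zero
noise: IDD = I₀_D(1−E)B_D, IAA = I₀_A·B_A, and
IDA = G·E·I₀_D·B_D + a·IAA + d·IDD, with bi-exponential bleach factors
B. Defaults: a = 0.08, d = 0.12, G = 2.0, I₀_D = 1000, I₀_A = 800
counts, 50-ms frames, 1% multiplicative shot noise, donor bleach
(A=0.3, τ₁=100 s, τ₂=1000 s), acceptor bleach (A=0.3, τ₁=150 s,
τ₂=2000 s). None of these optical values is reported for the real
setup; they are field-plausible magnitudes chosen once.

Bleach correction fits IDD and IAA to I₀(A·e^(−t/τ₁)+(1−A)e^(−t/τ₂))
with bounded least squares (A∈[0,1], τ>0; τ₁ ≤ τ₂ canonicalized after
the fit; near-constant traces short-circuit to a no-op). Frames inside
stimulus-response and saturating windows are excluded from the fit —
they carry signal that would otherwise be absorbed into the decay —
but the correction divides every frame. IDA is divided by the *donor*
decay, since its sensitized component bleaches with the donor; the
a·IAA cross-talk term actually decays with the acceptor, so this
correction is exact only when the two decays coincide. With the
default mild bleaching the residual systematic in normalized activity
is below 0.02, which is why the adaptation-time band floor is set to
0.02 (2% of the dynamic range) rather than machine precision.

E_app frames whose denominator magnitude falls below 10⁻⁶ × median IDD
are masked NaN instead of clipped — low-signal frames should disappear,
not manufacture fake efficiencies. Normalization is per cell, between
saturating-window means, with the kinase-ON = high-FRET polarity of the
CheY-mRFP/CheZ-mYFP pair as the default (configurable). Constants a
and d are calibrated as median IDA/IAA over acceptor-only cells and
median IDA/IDD over donor-only cells; G comes from config or from
acceptor-photobleach pairs ΔIDA/ΔIDD, with provenance recorded.

Adaptation time: baseline mean and SD from the pre-stimulus window
(skipping saturating segments plus a 2-s margin so smoothing cannot
bleed them in), response detected when the post-stimulus extremum
exceeds twice the band, and adaptation measured as the first re-entry
into baseline ± max(2·SD, 0.02) that holds for 5 s. The trace is
pre-smoothed with a 1-s running average; without it, per-frame shot
noise makes a 100-frame hold essentially impossible even for a fully
adapted cell. The search stops at the next scheduled disturbance so
removal responses are not mistaken for the extremum.

## Ring rendering and z-localization

Ring diameter vs height is linear: diameter = d₀ + slope·z, default
d₀ = 6 px, slope = 0.8 px/µm over 0–150 µm (the calibration is always
supplied as data, never assumed by the analysis). Rendered images are
radially symmetric Gaussian annuli (default 192-px frames, PSF width
2 px, amplitude 1, background noise SD 0.05, optional sub-pixel center
offset). The estimator refines the center by intensity centroid,
profiles intensity in 0.25-px annular bins with linear interpolation
of each pixel between adjacent bins, and locates the peak with
quadratic sub-bin interpolation; quality is peak prominence over the
border-estimated background SD, with a detection failure below 3.
Peaks within 1 px of the center are flagged as in-focus spots. Under
the defaults this localizes cells with z RMSE ≈ 0.25 µm, inside the
assay's stated ~0.5 µm resolution; the error scales roughly linearly
with background noise over the tested range. Out-of-range z values
are clamped and flagged rather than discarded so census totals are
conserved.

Colony comparisons pair replicate plates: the paired Student's t-test
runs on per-replicate mean z between each condition and the control
(the conservative pairing unit; per-cell pairing is not meaningful
across separately-grown colonies). The synthetic scenarios are a
surface-avoiding condition (truncated normal, mean 110 µm, SD 25 µm)
and a uniform condition over the colony height — these reproduce the
qualitative contrast between avoidance and its absence, not any
measured density profile.

## What the synthetic data does not emulate

Real bead recordings include load changes, motor speed fluctuations,
incomplete tethering and camera artifacts; real FRET data include
segmentation noise, background fluorescence, focus drift and
cell-to-cell expression variability; real defocused images include
asymmetric aberrations, overlapping rings and depth-dependent PSF
shape. Passing the suite therefore demonstrates the estimators are
correct and well-calibrated on their stated models, not that they are
robust to every instrumental pathology. The stimulus-to-rate kinetics
(step plus exponential relaxation) are placeholders for dynamics that
are not quantified; only the endpoint statistics they reproduce are
constrained.

## Problem sizes

Estimator-recovery runs use 200 motors × 10 min at 250 frames/s;
the null-calibration check uses 100 meta-replicates of 10 motors ×
2 min at 100 frames/s; the FRET pipeline check uses 50 cells × 240 s
at 20 frames/s; z-localization uses 2,500 rendered rings (500 per
seed × 5 seeds). All randomness flows through explicitly passed
seeded generators; identical seeds give byte-identical outputs.
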