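"""Ground-truthed forward models for every analysis stage.

Three generators mirror the three measurement pipelines:

* :func:`simulate_motor_trace` — a two-state (CW/CCW) continuous-time
  Markov motor, sampled exactly via its jump chain, driving an orbiting
  bead whose x/y positions are what the bead assay records.
* :func:`simulate_fret_experiment` — three-channel fluorescence
  intensities under a step-stimulus/adaptation kinase model with
  bi-exponential photobleaching and channel cross-talk.  By construction
  the E-FRET equation applied to the noiseless channels returns the
  ground-truth efficiency exactly.
* :func:`simulate_ring_observations` / :func:`render_ring_image` —
  defocused diffraction-ring diameters (or small synthetic ring images)
  under a linear diameter-vs-height calibration.

All randomness flows through a single ``numpy.random.Generator`` created
from the caller's seed; the same seed and parameters give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .types import (
    CCW,
    CW,
    PAUSE,
    EfretConstants,
    FretExperiment,
    MotorTrace,
    DirectionSeries,
    RingCalibration,
    RingObservation,
    StimulusSchedule,
)

__all__ = [
    "SwitchingModel",
    "KinaseStepModel",
    "BleachModel",
    "JumpPath",
    "MotorSimulation",
    "FretSimulation",
    "simulate_jump_path",
    "trace_from_path",
    "simulate_motor_trace",
    "simulate_fret_experiment",
    "simulate_single_label_experiment",
    "simulate_ring_observations",
    "render_ring_image",
]


# ---------------------------------------------------------------------------
# motor switching
# ---------------------------------------------------------------------------

@dataclass
class SwitchingModel:
    """Two-state CW/CCW switching model with optional stimulus overrides.

    ``rate_ccw_to_cw`` and ``rate_cw_to_ccw`` are the baseline transition
    rates (events/s).  ``stimulus_rate_map`` is a list of
    ``(t_start, t_end, rate_ccw_to_cw, rate_cw_to_ccw)`` windows that
    override the baseline; later entries win where windows overlap.

    The stationary CW bias is ``k1 / (k1 + k2)`` and the stationary
    switching-event rate is ``2 k1 k2 / (k1 + k2)`` where ``k1`` is
    CCW->CW and ``k2`` is CW->CCW.
    """

    rate_ccw_to_cw: float
    rate_cw_to_ccw: float
    speed_hz: float = 10.0
    pause_prob_per_switch: float = 0.0
    pause_dwell_s: float = 0.1
    stimulus_rate_map: list[tuple[float, float, float, float]] = field(
        default_factory=list)

    def __post_init__(self):
        if self.rate_ccw_to_cw < 0 or self.rate_cw_to_ccw < 0:
            raise InvalidArgumentError("switching rates must be >= 0")
        if self.speed_hz <= 0:
            raise InvalidArgumentError("speed_hz must be > 0")
        if not 0.0 <= self.pause_prob_per_switch <= 1.0:
            raise InvalidArgumentError("pause_prob_per_switch must be in [0, 1]")
        for t0, t1, k1, k2 in self.stimulus_rate_map:
            if t1 <= t0:
                raise InvalidArgumentError("rate-map window must have t_end > t_start")
            if k1 < 0 or k2 < 0:
                raise InvalidArgumentError("rate-map rates must be >= 0")

    @property
    def stationary_cw_bias(self) -> float:
        total = self.rate_ccw_to_cw + self.rate_cw_to_ccw
        if total == 0:
            raise InvalidArgumentError("both rates zero: stationary bias undefined")
        return self.rate_ccw_to_cw / total

    @property
    def stationary_switch_rate(self) -> float:
        """Expected CW<->CCW events per second at stationarity."""
        total = self.rate_ccw_to_cw + self.rate_cw_to_ccw
        if total == 0:
            return 0.0
        return 2.0 * self.rate_ccw_to_cw * self.rate_cw_to_ccw / total

    def rates_at(self, t: float) -> tuple[float, float]:
        k1, k2 = self.rate_ccw_to_cw, self.rate_cw_to_ccw
        for t0, t1, o1, o2 in self.stimulus_rate_map:
            if t0 <= t < t1:
                k1, k2 = o1, o2
        return k1, k2

    def breakpoints(self, duration: float) -> np.ndarray:
        pts = {0.0, duration}
        for t0, t1, *_ in self.stimulus_rate_map:
            for p in (t0, t1):
                if 0.0 < p < duration:
                    pts.add(float(p))
        return np.array(sorted(pts))


@dataclass
class JumpPath:
    """Exact continuous-time state path: segment boundaries and states.

    ``times[i]`` is the entry time of segment ``i`` with state
    ``states[i]``; the last segment ends at ``t_end``.
    """

    times: np.ndarray       # s, segment entry times, times[0] == 0
    states: np.ndarray      # int8 codes (CW/CCW/PAUSE)
    t_end: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)

    def state_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def n_switches(self, window: tuple[float, float] | None = None) -> int:
        """Count CW<->CCW reversals, bridging pauses.

        A reversal is counted at the entry time of a non-pause segment
        whose state differs from the last preceding non-pause state;
        CCW->PAUSE->CCW therefore counts zero, CCW->PAUSE->CW one.
        """
        t0, t1 = window if window is not None else (-np.inf, np.inf)
        count = 0
        last_np: int | None = None
        for t, s in zip(self.times, self.states):
            if s == PAUSE:
                continue
            if last_np is not None and s != last_np and t0 <= t < t1:
                count += 1
            last_np = int(s)
        return count

    def angle_at(self, t: np.ndarray, speed_hz: float,
                 theta0: float = 0.0) -> np.ndarray:
        """Integrated bead angle (rad, math convention: CCW positive).

        CW segments advance the angle at ``-2*pi*speed_hz`` rad/s, CCW at
        ``+2*pi*speed_hz``, pauses not at all.
        """
        t = np.asarray(t, dtype=float)
        bounds = np.append(self.times, self.t_end)
        # angular velocity per segment; state CW=+1 spins the angle down
        omega = -2.0 * np.pi * speed_hz * self.states.astype(float)
        seg_dt = np.diff(bounds)
        theta_bounds = theta0 + np.concatenate(
            [[0.0], np.cumsum(omega * seg_dt)])
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1,
                      0, len(self.states) - 1)
        return theta_bounds[idx] + omega[idx] * (t - self.times[idx])


def simulate_jump_path(model: SwitchingModel, duration: float,
                       rng: np.random.Generator,
                       initial_state: int | None = None) -> JumpPath:
    """Sample the exact two-state jump chain over ``[0, duration]``.

    Within each piecewise-constant rate window, dwell times are
    exponential with the state's exit rate; crossing a window boundary
    resamples the dwell (valid by memorylessness).
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    k1_0, k2_0 = model.rates_at(0.0)
    if initial_state is None:
        total = k1_0 + k2_0
        if total == 0:
            raise InvalidArgumentError(
                "both switching rates are zero at t=0; supply initial_state")
        p_cw = k1_0 / total
        state = CW if rng.random() < p_cw else CCW
    else:
        if initial_state not in (CW, CCW):
            raise InvalidArgumentError("initial_state must be CW or CCW")
        state = initial_state

    bps = model.breakpoints(duration)
    times = [0.0]
    states = [state]
    t = 0.0
    bp_idx = 0
    while t < duration:
        while bp_idx + 1 < len(bps) and bps[bp_idx + 1] <= t:
            bp_idx += 1
        seg_end = bps[bp_idx + 1] if bp_idx + 1 < len(bps) else duration
        k1, k2 = model.rates_at(t)
        exit_rate = k1 if state == CCW else k2
        if exit_rate == 0.0:
            t = seg_end
            continue
        dwell = rng.exponential(1.0 / exit_rate)
        if t + dwell >= seg_end:
            t = seg_end   # no jump; memoryless resample in next window
            continue
        t += dwell
        new_state = CW if state == CCW else CCW
        if (model.pause_prob_per_switch > 0
                and rng.random() < model.pause_prob_per_switch):
            times.append(t)
            states.append(PAUSE)
            t = min(t + model.pause_dwell_s, duration)
            if t >= duration:
                break
        times.append(t)
        states.append(new_state)
        state = new_state
    return JumpPath(np.array(times), np.array(states, dtype=np.int8),
                    t_end=float(duration))


@dataclass
class MotorSimulation:
    """Simulated bead recording plus its ground truth."""

    trace: MotorTrace
    truth: DirectionSeries
    path: JumpPath
    model: SwitchingModel

    def __iter__(self):  # allows  trace, truth = simulate_motor_trace(...)
        return iter((self.trace, self.truth))


def trace_from_path(path: JumpPath, model: SwitchingModel, fps: float,
                    orbit_radius: float, position_noise_sd: float,
                    rng: np.random.Generator,
                    center: tuple[float, float] = (0.0, 0.0),
                    theta0: float = 0.0) -> MotorSimulation:
    """Discretize an exact jump path into a noisy bead-position trace."""
    if fps <= 0:
        raise InvalidArgumentError("fps must be > 0")
    n = int(round(path.t_end * fps))
    t = np.arange(n) / fps
    theta = path.angle_at(t, model.speed_hz, theta0=theta0)
    x = center[0] + orbit_radius * np.cos(theta)
    y = center[1] + orbit_radius * np.sin(theta)
    if position_noise_sd > 0:
        x = x + rng.normal(0.0, position_noise_sd, n)
        y = y + rng.normal(0.0, position_noise_sd, n)
    trace = MotorTrace(t=t, x=x, y=y, fps=fps,
                       metadata={"orbit_radius_um": orbit_radius,
                                 "position_noise_sd_um": position_noise_sd})
    state = path.state_at(t)
    truth = DirectionSeries(t=t, state=state,
                            signed_speed_hz=state.astype(float) * model.speed_hz)
    return MotorSimulation(trace=trace, truth=truth, path=path, model=model)


def simulate_motor_trace(model: SwitchingModel, duration: float, fps: float,
                         orbit_radius: float = 0.25,
                         position_noise_sd: float = 0.01,
                         seed: int | np.random.Generator = 0,
                         initial_state: int | None = None) -> MotorSimulation:
    """Simulate one bead-assay recording with ground truth.

    Parameters use the assay's physical units: ``duration`` s, ``fps``
    frames/s, ``orbit_radius`` and ``position_noise_sd`` um.
    """
    if duration <= 0 or fps <= 0:
        raise InvalidArgumentError("duration and fps must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    path = simulate_jump_path(model, duration, rng, initial_state=initial_state)
    theta0 = float(rng.uniform(0.0, 2.0 * np.pi))
    return trace_from_path(path, model, fps, orbit_radius,
                           position_noise_sd, rng, theta0=theta0)


# ---------------------------------------------------------------------------
# FRET forward model
# ---------------------------------------------------------------------------

@dataclass
class KinaseStepModel:
    """Phenomenological step-plus-adaptation kinase-activity model.

    On stimulus addition the activity jumps from ``baseline_activity`` to
    ``peak_activity`` and relaxes back exponentially with
    ``adaptation_tau`` (adaptation); on removal it undershoots the
    baseline by ``removal_undershoot`` and recovers with
    ``recovery_tau``.  FRET efficiency is an affine map of activity
    between ``e_min`` and ``e_max``.
    """

    baseline_activity: float = 0.3
    peak_activity: float = 0.9
    adaptation_tau: float = 20.0
    removal_undershoot: float = 0.2
    recovery_tau: float = 20.0
    e_min: float = 0.10
    e_max: float = 0.45

    def __post_init__(self):
        if not (0.0 <= self.e_min < self.e_max <= 1.0):
            raise InvalidArgumentError("require 0 <= e_min < e_max <= 1")
        for name in ("baseline_activity", "peak_activity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.adaptation_tau <= 0 or self.recovery_tau <= 0:
            raise InvalidArgumentError("time constants must be > 0")

    def activity(self, t: np.ndarray,
                 schedule: StimulusSchedule) -> np.ndarray:
        """Ground-truth activity trajectory, clipped to [0, 1].

        Saturating-window overrides force activity to 0 (min windows) or
        1 (max windows), emulating the saturating stimuli used for
        per-cell normalization.
        """
        t = np.asarray(t, dtype=float)
        a = np.full_like(t, self.baseline_activity)
        for ev in sorted(schedule.events, key=lambda e: e.time):
            m = t >= ev.time
            if ev.kind == "add":
                a[m] = (self.baseline_activity
                        + (self.peak_activity - self.baseline_activity)
                        * np.exp(-(t[m] - ev.time) / self.adaptation_tau))
            else:
                a[m] = (self.baseline_activity
                        - self.removal_undershoot
                        * np.exp(-(t[m] - ev.time) / self.recovery_tau))
        for w in schedule.saturating_windows:
            m = (t >= w.t_start) & (t < w.t_end)
            a[m] = 0.0 if w.expected_extreme == "min" else 1.0
        return np.clip(a, 0.0, 1.0)

    def efficiency(self, activity: np.ndarray) -> np.ndarray:
        return self.e_min + (self.e_max - self.e_min) * np.asarray(activity)


@dataclass
class BleachModel:
    """Bi-exponential photobleaching decay, normalized to 1 at t = 0."""

    amp1: float = 0.3
    tau1: float = 100.0
    amp2: float | None = None     # defaults to 1 - amp1
    tau2: float = 1000.0

    def __post_init__(self):
        if self.amp2 is None:
            self.amp2 = 1.0 - self.amp1
        if self.amp1 < 0 or self.amp2 < 0:
            raise InvalidArgumentError("amplitudes must be >= 0")
        if abs(self.amp1 + self.amp2 - 1.0) > 1e-9:
            raise InvalidArgumentError("amp1 + amp2 must equal 1 at t = 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidArgumentError("decay times must be > 0")

    def decay(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amp1 * np.exp(-t / self.tau1) + self.amp2 * np.exp(-t / self.tau2)

    @classmethod
    def none(cls) -> "BleachModel":
        """No bleaching (both decay constants effectively infinite)."""
        return cls(amp1=0.5, tau1=1e12, amp2=0.5, tau2=1e12)


@dataclass
class FretSimulation:
    experiment: FretExperiment
    efret_true: np.ndarray
    activity_true: np.ndarray
    kinase: KinaseStepModel
    constants: EfretConstants

    def __iter__(self):
        return iter((self.experiment, self.efret_true))


def simulate_fret_experiment(kinase: KinaseStepModel,
                             bleach_donor: BleachModel,
                             bleach_acceptor: BleachModel,
                             constants: EfretConstants,
                             schedule: StimulusSchedule,
                             duration: float = 240.0,
                             dt: float = 0.05,
                             i0_donor: float = 1000.0,
                             i0_acceptor: float = 800.0,
                             shot_noise_sd: float = 0.01,
                             seed: int | np.random.Generator = 0,
                             cell_id: str = "cell") -> FretSimulation:
    """Generate a three-channel FRET recording with known efficiency.

    The noiseless channels satisfy, for every frame,

        IDD = I0_D (1 - E) B_D,  IAA = I0_A B_A,
        IDA = G E I0_D B_D + a IAA + d IDD,

    so that the E-FRET expression recovers E(t) exactly; multiplicative
    Gaussian shot noise (fractional SD ``shot_noise_sd``) is applied
    last.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.arange(0.0, duration, dt)
    for w in schedule.saturating_windows:
        if w.t_end > duration + 1e-9:
            raise InvalidArgumentError("saturating window extends past duration")
    for ev in schedule.events:
        if not 0.0 <= ev.time <= duration:
            raise InvalidArgumentError("stimulus event outside recording")

    activity = kinase.activity(t, schedule)
    e_true = kinase.efficiency(activity)
    b_d = bleach_donor.decay(t)
    b_a = bleach_acceptor.decay(t)
    idd = i0_donor * (1.0 - e_true) * b_d
    iaa = i0_acceptor * b_a
    ida = constants.G * e_true * i0_donor * b_d + constants.a * iaa + constants.d * idd
    if shot_noise_sd > 0:
        idd = idd * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
        ida = ida * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
        iaa = iaa * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
        idd, ida, iaa = (np.clip(c, 0.0, None) for c in (idd, ida, iaa))
    exp = FretExperiment(t=t, idd=idd, ida=ida, iaa=iaa, schedule=schedule,
                         cell_id=cell_id, bleach_corrected=shot_noise_sd == 0
                         and bleach_donor.decay(np.array([duration]))[0] > 1 - 1e-12)
    return FretSimulation(experiment=exp, efret_true=e_true,
                          activity_true=activity, kinase=kinase,
                          constants=constants)


def simulate_single_label_experiment(kind: str,
                                     constants: EfretConstants,
                                     bleach: BleachModel,
                                     duration: float = 60.0,
                                     dt: float = 0.05,
                                     i0: float = 1000.0,
                                     shot_noise_sd: float = 0.0,
                                     seed: int | np.random.Generator = 0,
                                     cell_id: str = "cal") -> FretExperiment:
    """Single-fluorophore control used to calibrate the constants a and d.

    ``kind='acceptor'``: only the acceptor present, so IDD = 0 and
    IDA = a * IAA.  ``kind='donor'``: only the donor present (no
    transfer), so IAA = 0 and IDA = d * IDD.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.arange(0.0, duration, dt)
    b = bleach.decay(t)
    zeros = np.zeros_like(t)
    if kind == "acceptor":
        iaa = i0 * b
        ida = constants.a * iaa
        idd = zeros
    elif kind == "donor":
        idd = i0 * b
        ida = constants.d * idd
        iaa = zeros
    else:
        raise InvalidArgumentError("kind must be 'donor' or 'acceptor'")
    if shot_noise_sd > 0:
        idd = idd * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
        ida = ida * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
        iaa = iaa * (1.0 + rng.normal(0.0, shot_noise_sd, len(t)))
    return FretExperiment(t=t, idd=idd, ida=ida, iaa=iaa, cell_id=cell_id)


# ---------------------------------------------------------------------------
# defocused diffraction rings
# ---------------------------------------------------------------------------

def simulate_ring_observations(calibration: RingCalibration,
                               z_positions,
                               seed: int | np.random.Generator = 0,
                               condition: str = "",
                               replicate: str = "") -> list[RingObservation]:
    """Ring diameters for cells at known heights, with ground truth kept."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z = np.asarray(z_positions, dtype=float)
    z_lo, z_hi = calibration.z_range
    if np.any(z < z_lo - 1e-12) or np.any(z > z_hi + 1e-12):
        raise InvalidArgumentError("z position outside calibration z_range")
    d = calibration.diameter_at(z)
    if calibration.noise_sd > 0:
        d = d + rng.normal(0.0, calibration.noise_sd, len(z))
    d = np.clip(d, 0.0, None)
    return [RingObservation(diameter_px=float(di), z_true_um=float(zi),
                            condition=condition, replicate=replicate)
            for di, zi in zip(d, z)]


def render_ring_image(z: float, calibration: RingCalibration,
                      image_size: int = 192, psf_width: float = 2.0,
                      background_sd: float = 0.05,
                      amplitude: float = 1.0,
                      center_offset: tuple[float, float] = (0.0, 0.0),
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Render one defocused diffraction ring as a 2-D intensity image.

    The ring is a radially symmetric Gaussian annulus of nominal
    diameter ``d0 + slope*z`` centered at the image center plus an
    optional sub-pixel ``center_offset``; i.i.d. Gaussian background
    noise of SD ``background_sd`` is added on top.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z_lo, z_hi = calibration.z_range
    if not z_lo - 1e-12 <= z <= z_hi + 1e-12:
        raise InvalidArgumentError("z outside calibration z_range")
    diameter = float(calibration.diameter_at(z))
    if diameter + 6.0 * psf_width >= image_size:
        raise InvalidArgumentError(
            f"ring (diameter {diameter:.1f} px + PSF margin) does not fit in "
            f"a {image_size}-px image")
    c = (image_size - 1) / 2.0
    cy, cx = c + center_offset[1], c + center_offset[0]
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - cy, xx - cx)
    img = amplitude * np.exp(-((r - diameter / 2.0) ** 2)
                             / (2.0 * psf_width ** 2))
    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, img.shape)
    return img
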