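"""E-FRET kinase-activity analysis.

The three-cube (sensitized-emission) apparent FRET efficiency is

    E_app = (IDA - a*IAA - d*IDD) / (IDA - a*IAA + (G - d)*IDD)

with bleed-through constants ``a`` (acceptor direct excitation into the
FRET channel) and ``d`` (donor emission into the FRET channel) and the
gauge factor ``G``.  Photobleaching is corrected beforehand by fitting
the donor (IDD) and acceptor (IAA) traces to bi-exponential decays and
dividing each channel by its normalized decay; the FRET channel IDA,
whose sensitized component bleaches with the donor, is divided by the
donor decay.  Per-cell kinase activity is E_app rescaled between the
means measured in saturating-stimulus windows at the start and end of
the experiment, so 0-1 spans kinase-OFF to kinase-ON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .errors import (
    CalibrationError,
    FitError,
    InvalidArgumentError,
    NormalizationError,
    SignalTooWeakError,
)
from .synthetic import BleachModel
from .types import (
    EfretConstants,
    FretExperiment,
    KinaseActivitySeries,
    StimulusSchedule,
)

__all__ = [
    "fit_bleach_correction",
    "correct_experiment",
    "calibrate_constants",
    "compute_efret",
    "normalize_activity",
    "AdaptationEstimate",
    "estimate_adaptation_time",
]


def _biexp(t, i0, amp1, tau1, tau2):
    return i0 * (amp1 * np.exp(-t / tau1) + (1.0 - amp1) * np.exp(-t / tau2))


def fit_bleach_correction(t: np.ndarray, intensity: np.ndarray,
                          exclude_windows: list[tuple[float, float]] | None = None,
                          ) -> tuple[BleachModel, np.ndarray]:
    """Fit I(t) = I0*(A exp(-t/tau1) + (1-A) exp(-t/tau2)); return the
    decay model and the corrected series raw/decay (decay normalized to
    1 at t = 0).

    Frames inside ``exclude_windows`` (stimulus-response intervals) are
    dropped from the fit so the correction stays signal-agnostic, but
    the correction is applied to every frame.
    """
    t = np.asarray(t, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    fit_mask = np.ones(len(t), dtype=bool)
    for t0, t1 in exclude_windows or []:
        fit_mask &= ~((t >= t0) & (t < t1))
    if np.sum(fit_mask) < 50:
        raise InvalidArgumentError(
            "need >= 50 frames outside excluded windows for a bleach fit")
    tf, yf = t[fit_mask], intensity[fit_mask]
    scale = float(np.median(yf))
    if scale <= 0:
        raise FitError("non-positive median intensity")
    # near-constant trace: the decay is unidentifiable, correction is a no-op
    if np.std(yf) / scale < 1e-9:
        return BleachModel.none(), intensity.copy()
    span = tf[-1] - tf[0]
    p0 = (float(yf[0]), 0.5, span / 5.0, span * 5.0)
    bounds = ([0.0, 0.0, 1e-3, 1e-3], [np.inf, 1.0, 1e9, 1e9])
    try:
        popt, _ = curve_fit(_biexp, tf, yf, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((yf - _biexp(tf, *p0)) ** 2)))
        raise FitError(f"bi-exponential fit failed: {exc}", residual=resid)
    i0, amp1, tau1, tau2 = popt
    if tau1 > tau2:   # canonical order: tau1 is the fast component
        tau1, tau2 = tau2, tau1
        amp1 = 1.0 - amp1
    model = BleachModel(amp1=float(amp1), tau1=float(tau1),
                        amp2=float(1.0 - amp1), tau2=float(tau2))
    decay = model.decay(t)
    return model, intensity / decay


def correct_experiment(exp: FretExperiment,
                       exclude_windows: list[tuple[float, float]] | None = None,
                       ) -> tuple[FretExperiment, BleachModel, BleachModel]:
    """Photobleach-correct all three channels of an experiment.

    IDD and IAA get their own fitted decays; IDA is divided by the donor
    decay (its sensitized-emission component bleaches with the donor).
    """
    donor_model, idd_c = fit_bleach_correction(exp.t, exp.idd, exclude_windows)
    acc_model, iaa_c = fit_bleach_correction(exp.t, exp.iaa, exclude_windows)
    ida_c = exp.ida / donor_model.decay(exp.t)
    corrected = FretExperiment(t=exp.t, idd=idd_c, ida=ida_c, iaa=iaa_c,
                               schedule=exp.schedule, cell_id=exp.cell_id,
                               bleach_corrected=True)
    return corrected, donor_model, acc_model


def calibrate_constants(donor_only: list[FretExperiment],
                        acceptor_only: list[FretExperiment],
                        G: float | None = None,
                        acceptor_bleach_pairs: list[tuple[float, float]] | None = None,
                        ) -> EfretConstants:
    """Derive the optical constants from single-fluorophore controls.

    ``a`` is the median of IDA/IAA over all frames of acceptor-only
    cells; ``d`` the median of IDA/IDD over donor-only cells.  ``G``
    comes either from config or from acceptor-photobleach pairs
    ``(delta_IDA_sensitized, delta_IDD)`` as the median ratio.
    """
    if not donor_only or not acceptor_only:
        raise InvalidArgumentError("single-label experiment sets must be nonempty")

    def _median_ratio(exps, num_attr, den_attr, name):
        nums, dens = [], []
        for e in exps:
            nums.append(getattr(e, num_attr))
            dens.append(getattr(e, den_attr))
        num = np.concatenate(nums)
        den = np.concatenate(dens)
        ok = den > 1e-9 * max(float(np.median(np.abs(den))), 1e-12)
        if not np.any(ok):
            raise CalibrationError(f"{name}: denominator channel is ~0 everywhere")
        return float(np.median(num[ok] / den[ok]))

    a = _median_ratio(acceptor_only, "ida", "iaa", "a = IDA/IAA")
    d = _median_ratio(donor_only, "ida", "idd", "d = IDA/IDD")
    if G is not None:
        g_val, prov = float(G), "config"
    elif acceptor_bleach_pairs:
        ratios = [dida / didd for dida, didd in acceptor_bleach_pairs
                  if abs(didd) > 1e-12]
        if not ratios:
            raise CalibrationError("acceptor-bleach pairs have ~0 donor change")
        g_val, prov = float(np.median(ratios)), "acceptor-photobleach pairs"
    else:
        raise InvalidArgumentError("supply G or acceptor_bleach_pairs")
    return EfretConstants(a=a, d=d, G=g_val, g_provenance=prov)


def compute_efret(exp: FretExperiment, constants: EfretConstants,
                  denominator_floor_factor: float = 1e-6) -> np.ndarray:
    """Per-frame apparent FRET efficiency.

    Frames whose denominator magnitude falls below
    ``denominator_floor_factor`` times the median IDD are masked NaN
    rather than returned as spikes.
    """
    if not exp.bleach_corrected:
        warnings.warn("channels are not flagged as bleach-corrected; E_app may "
                      "drift over the recording", stacklevel=2)
    num = exp.ida - constants.a * exp.iaa - constants.d * exp.idd
    den = exp.ida - constants.a * exp.iaa + (constants.G - constants.d) * exp.idd
    floor = denominator_floor_factor * float(np.median(exp.idd))
    bad = np.abs(den) < floor
    if np.all(bad):
        raise SignalTooWeakError("every frame fell below the denominator floor")
    e = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return e


def normalize_activity(t: np.ndarray, e_app: np.ndarray,
                       schedule: StimulusSchedule,
                       kinase_high_fret: bool = True) -> KinaseActivitySeries:
    """Rescale E_app per cell between saturating-window means.

    With the default polarity (``kinase_high_fret=True``, the
    CheY-mRFP/CheZ-mYFP pair) high FRET means high kinase activity, so
    activity = (E - E_sat_min)/(E_sat_max - E_sat_min), clipped to
    [0, 1].
    """
    t = np.asarray(t, dtype=float)
    e_app = np.asarray(e_app, dtype=float)
    mins = schedule.windows("min")
    maxs = schedule.windows("max")
    if not mins or not maxs:
        raise InvalidArgumentError(
            "schedule needs at least one 'min' and one 'max' saturating window")

    def _window_mean(wins):
        vals = []
        for w in wins:
            m = (t >= w.t_start) & (t < w.t_end)
            if np.any(m):
                vals.append(np.nanmean(e_app[m]))
        if not vals:
            raise InvalidArgumentError("saturating window contains no frames")
        return float(np.mean(vals))

    e_lo = _window_mean(mins)
    e_hi = _window_mean(maxs)
    if e_hi <= e_lo:
        raise NormalizationError(
            f"saturating max ({e_hi:.4g}) <= min ({e_lo:.4g}); windows are "
            "likely mislabeled")
    activity = (e_app - e_lo) / (e_hi - e_lo)
    if not kinase_high_fret:
        activity = 1.0 - activity
    activity = np.clip(activity, 0.0, 1.0)
    first_stim = schedule.first_event_time()
    baseline = None
    if first_stim is not None:
        mask = t < first_stim   # pre-stimulus, excluding saturating frames
        for w in schedule.saturating_windows:
            mask &= ~((t >= w.t_start) & (t < w.t_end))
        pre = activity[mask & ~np.isnan(activity)]
        if len(pre):
            baseline = float(np.mean(pre))
    return KinaseActivitySeries(t=t, activity=activity, baseline=baseline)


def default_exclude_windows(schedule: StimulusSchedule,
                            response_s: float = 60.0,
                            margin: float = 2.0,
                            ) -> list[tuple[float, float]]:
    """Windows to drop from bleach fits: stimulus responses and
    saturating calibration segments (both carry signal, which would
    otherwise be absorbed into the fitted decay)."""
    wins = [(e.time, e.time + response_s) for e in schedule.events]
    wins += [(w.t_start, w.t_end + margin) for w in schedule.saturating_windows]
    return wins


def adaptation_search_end(schedule: StimulusSchedule,
                          stimulus_time: float) -> float | None:
    """End of the adaptation search: the next scheduled disturbance
    (stimulus event or saturating window) after ``stimulus_time``."""
    later = [e.time for e in schedule.events if e.time > stimulus_time]
    later += [w.t_start for w in schedule.saturating_windows
              if w.t_start > stimulus_time]
    return min(later) if later else None


def baseline_window_from_schedule(schedule: StimulusSchedule,
                                  stimulus_time: float,
                                  margin: float = 2.0,
                                  ) -> tuple[float, float]:
    """Pre-stimulus window that skips saturating calibration segments.

    ``margin`` seconds are dropped after each saturating window so that
    running-average smoothing cannot bleed the saturated level into the
    baseline estimate.
    """
    t0 = 0.0
    for w in schedule.saturating_windows:
        if w.t_end <= stimulus_time:
            t0 = max(t0, w.t_end + margin)
    return (t0, stimulus_time)


@dataclass
class AdaptationEstimate:
    """Outcome of the adaptation-time measurement.

    ``time`` is seconds from stimulus to stable re-entry into the
    baseline band, or None; ``responded`` is False when no post-stimulus
    extremum rose above the detection band.
    """

    time: float | None
    responded: bool
    baseline: float
    baseline_sd: float
    extremum: float
    extremum_time: float


def estimate_adaptation_time(series: KinaseActivitySeries,
                             stimulus_time: float,
                             k: float = 2.0,
                             hold: float = 5.0,
                             band_floor: float = 0.02,
                             baseline_window: tuple[float, float] | None = None,
                             smooth: float = 1.0,
                             t_max: float | None = None,
                             ) -> AdaptationEstimate:
    """Time for activity to re-enter the baseline band after a stimulus.

    Baseline mean and SD come from ``baseline_window`` (default: all
    pre-stimulus frames; pass an explicit window to skip saturating
    calibration segments at the start of the recording; >= 10 s
    required).  The adaptation time is the first time after the
    post-stimulus extremum at which activity is within
    baseline +/- max(k*SD, band_floor) and stays there for ``hold``
    seconds.  The trace is pre-smoothed with a centered ``smooth``-s
    running average so per-frame shot noise does not veto the hold, and
    the search stops at ``t_max`` (pass the next scheduled disturbance,
    e.g. via :func:`adaptation_search_end`, so removal responses or
    saturating windows are not mistaken for the response extremum).
    """
    t = series.t
    a = series.activity
    if smooth > 0 and len(t) > 2:
        dt = float(np.median(np.diff(t)))
        size = max(1, int(round(smooth / dt)))
        filled = np.where(np.isnan(a), np.nanmedian(a), a)
        a = uniform_filter1d(filled, size=size, mode="nearest")
    if baseline_window is None:
        baseline_window = (-np.inf, stimulus_time)
    pre = (t >= baseline_window[0]) & (t < min(baseline_window[1],
                                               stimulus_time)) & ~np.isnan(a)
    if not np.any(pre) or (t[pre][-1] - t[pre][0]) < 10.0:
        raise InvalidArgumentError("need >= 10 s of pre-stimulus baseline")
    baseline = float(np.mean(a[pre]))
    sd = float(np.std(a[pre]))
    band = max(k * sd, band_floor)

    post = t >= stimulus_time
    if t_max is not None:
        post &= t < t_max
    dev = np.abs(np.where(np.isnan(a), baseline, a) - baseline)
    dev_post = dev[post]
    t_post = t[post]
    i_ext = int(np.argmax(dev_post))
    extremum = float(a[post][i_ext])
    ext_time = float(t_post[i_ext])
    if dev_post[i_ext] <= 2.0 * band:
        return AdaptationEstimate(time=None, responded=False,
                                  baseline=baseline, baseline_sd=sd,
                                  extremum=extremum, extremum_time=ext_time)

    within = dev_post <= band
    within[:i_ext + 1] = False
    candidates = np.flatnonzero(within)
    for i in candidates:
        t_i = t_post[i]
        hold_mask = (t_post >= t_i) & (t_post <= t_i + hold)
        if np.all(within[hold_mask]):
            # also accept truncated holds at end of trace
            return AdaptationEstimate(time=float(t_i - stimulus_time),
                                      responded=True, baseline=baseline,
                                      baseline_sd=sd, extremum=extremum,
                                      extremum_time=ext_time)
    return AdaptationEstimate(time=None, responded=True, baseline=baseline,
                              baseline_sd=sd, extremum=extremum,
                              extremum_time=ext_time)
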