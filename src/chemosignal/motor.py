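"""Bead-assay rotation analysis.

Turns a bead x/y trajectory into a per-frame rotation-direction series,
then into the assay's standard observables: CW bias (fraction of
non-pause time spent rotating clockwise), reversal rate (CW<->CCW
switching events per minute) and mean rotation speed, with a 30-s
running average of the bias and a Student's t comparison of pre- vs
post-stimulus summaries.

Sign convention: clockwise rotation is positive.  In standard
mathematical axes CCW is increasing angle, so signed speed is the
negated unwrapped angular velocity over 2*pi; recordings whose image
y-axis points down can set ``y_axis_down=True`` to flip chirality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    EstimationError,
    InsufficientReplicatesError,
    InvalidArgumentError,
    UndefinedBiasError,
)
from .types import CCW, CW, PAUSE, DirectionSeries, MotorSummary, MotorTrace

__all__ = [
    "RotationEstimate",
    "estimate_rotation",
    "classify_direction",
    "compute_cw_bias",
    "smooth_cw_bias",
    "count_reversals",
    "summarize_window",
    "compare_pre_post",
    "TTestResult",
]


@dataclass
class RotationEstimate:
    """Unwrapped bead angle and signed rotation speed."""

    t: np.ndarray                # s
    theta: np.ndarray            # rad, unwrapped, math convention
    signed_speed_hz: np.ndarray  # Hz, CW positive
    radius: float                # um, mean orbit radius
    fps: float


def _running_mean_truncated(v: np.ndarray, win: int) -> np.ndarray:
    """Centered running mean whose window truncates at the edges.

    Truncation (rather than edge padding) keeps the orbit-center
    estimate unbiased near the start and end of a recording.
    """
    n = len(v)
    half = win // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def estimate_rotation(trace: MotorTrace, center_window: float = 1.0,
                      y_axis_down: bool = False) -> RotationEstimate:
    """Estimate the bead's rotation angle and signed speed.

    The orbit center is a running centroid over ``center_window`` seconds
    (robust to slow stage drift); the angle is the unwrapped atan2 about
    that center and the angular velocity its central difference.
    """
    n = len(trace.t)
    if n < 10:
        raise InvalidArgumentError("need at least 10 frames")
    win = max(1, int(round(center_window * trace.fps)))
    cx = _running_mean_truncated(trace.x, win)
    cy = _running_mean_truncated(trace.y, win)
    dx = trace.x - cx
    dy = trace.y - cy
    r = np.hypot(dx, dy)
    radius = float(np.mean(r))
    if radius <= 0 or not np.isfinite(radius):
        raise EstimationError("degenerate trace: zero orbit radius")
    # high-frequency position jitter as a noise-floor estimate
    noise_sd = float(np.std(np.diff(trace.x)) / np.sqrt(2.0)) if n > 2 else 0.0
    if noise_sd > 0 and radius / noise_sd < 2.0:
        warnings.warn(
            f"orbit radius ({radius:.3g} um) is under 2x the position noise "
            f"floor ({noise_sd:.3g} um); direction calls may be unreliable",
            stacklevel=2)
    theta = np.unwrap(np.arctan2(dy, dx))
    omega = np.gradient(theta, trace.t)          # rad/s, CCW positive
    sign = 1.0 if y_axis_down else -1.0
    signed_speed = sign * omega / (2.0 * np.pi)  # CW positive
    return RotationEstimate(t=trace.t, theta=theta,
                            signed_speed_hz=signed_speed,
                            radius=radius, fps=trace.fps)


def _runs(values: np.ndarray) -> list[list[int]]:
    """Run-length encode into [value, length] pairs."""
    out: list[list[int]] = []
    for v in values:
        if out and out[-1][0] == v:
            out[-1][1] += 1
        else:
            out.append([int(v), 1])
    return out


def _debounce(runs: list[list[int]], min_frames: int) -> list[list[int]]:
    """Merge runs shorter than ``min_frames`` into their longer neighbor.

    Ties go to the preceding run; neighbors that become equal-valued are
    coalesced.  The earliest short run is merged first and the scan
    restarts, so the result is deterministic.
    """
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i in range(len(runs)):
            if runs[i][1] >= min_frames:
                continue
            prev_len = runs[i - 1][1] if i > 0 else -1
            next_len = runs[i + 1][1] if i + 1 < len(runs) else -1
            target = i - 1 if prev_len >= next_len else i + 1
            runs[target][1] += runs[i][1]
            del runs[i]
            merged: list[list[int]] = []
            for v, ln in runs:
                if merged and merged[-1][0] == v:
                    merged[-1][1] += ln
                else:
                    merged.append([v, ln])
            runs = merged
            changed = True
            break
    return runs


def classify_direction(rotation: RotationEstimate,
                       pause_threshold: float = 2.0,
                       min_dwell: float = 0.010) -> DirectionSeries:
    """Label each frame CW / CCW / PAUSE with hysteresis debouncing.

    Frames with |signed speed| below ``pause_threshold`` Hz are pauses;
    any run shorter than ``min_dwell`` seconds is merged into its longer
    flanking run (ties into the preceding run), which suppresses jitter
    at switch boundaries.  Deterministic.
    """
    if pause_threshold < 0 or min_dwell < 0:
        raise InvalidArgumentError("thresholds must be >= 0")
    speed = rotation.signed_speed_hz
    state = np.where(np.abs(speed) < pause_threshold, PAUSE,
                     np.where(speed > 0, CW, CCW)).astype(np.int8)

    min_frames = max(1, int(round(min_dwell * rotation.fps)))
    if min_frames > 1:
        runs = _debounce(_runs(state), min_frames)
        state = np.concatenate([np.full(ln, v, dtype=np.int8)
                                for v, ln in runs])
    if np.all(state == PAUSE):
        warnings.warn("all frames classified as PAUSE; motor may be stuck",
                      stacklevel=2)
    return DirectionSeries(t=rotation.t, state=state,
                           signed_speed_hz=np.where(state == PAUSE, 0.0, speed))


def compute_cw_bias(ds: DirectionSeries,
                    window: tuple[float, float] | None = None) -> float:
    """CW bias = CW time / (CW time + CCW time); pauses excluded."""
    m = ds.window_mask(window)
    s = ds.state[m]
    n_cw = int(np.sum(s == CW))
    n_ccw = int(np.sum(s == CCW))
    if n_cw + n_ccw == 0:
        raise UndefinedBiasError("window contains no non-pause frames")
    return n_cw / (n_cw + n_ccw)


def smooth_cw_bias(ds: DirectionSeries, window: float = 30.0) -> np.ndarray:
    """Centered running average of CW bias over ``window`` seconds.

    Edge frames use the truncated window that fits inside the recording;
    frames whose window holds no non-pause data are NaN.  If the whole
    recording is shorter than ``window`` the single whole-trace bias is
    broadcast (with a warning).
    """
    t = ds.t
    if len(t) < 2:
        raise InvalidArgumentError("need at least 2 frames")
    if t[-1] - t[0] < window:
        warnings.warn("recording shorter than smoothing window; returning the "
                      "whole-trace bias", stacklevel=2)
        return np.full(len(t), compute_cw_bias(ds))
    half = window / 2.0
    is_cw = np.cumsum(np.concatenate([[0], (ds.state == CW).astype(float)]))
    is_ccw = np.cumsum(np.concatenate([[0], (ds.state == CCW).astype(float)]))
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    n_cw = is_cw[hi] - is_cw[lo]
    n_ccw = is_ccw[hi] - is_ccw[lo]
    total = n_cw + n_ccw
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, n_cw / np.where(total > 0, total, 1), np.nan)
    return out


def count_reversals(ds: DirectionSeries,
                    window: tuple[float, float] | None = None,
                    per_minute: bool = True) -> float:
    """Count CW<->CCW reversals, bridging pauses.

    Consecutive non-pause frames with different states mark one
    reversal; a pause between opposite states counts once, a pause
    returning to the same state counts zero.
    """
    m = ds.window_mask(window)
    t = ds.t[m]
    s = ds.state[m]
    if len(t) == 0:
        return 0.0
    np_mask = s != PAUSE
    collapsed = s[np_mask]
    n = int(np.sum(collapsed[1:] != collapsed[:-1])) if len(collapsed) > 1 else 0
    if not per_minute:
        return float(n)
    duration = (window[1] - window[0]) if window is not None else float(t[-1] - t[0])
    if duration < 1.0:
        raise InvalidArgumentError("window must span at least 1 s for a rate")
    return n / duration * 60.0


def summarize_window(ds: DirectionSeries,
                     window: tuple[float, float] | None = None) -> MotorSummary:
    """Bundle CW bias, reversal rate and mean speed over a window."""
    m = ds.window_mask(window)
    s = ds.state[m]
    n_cw = int(np.sum(s == CW))
    n_ccw = int(np.sum(s == CCW))
    n_pause = int(np.sum(s == PAUSE))
    if n_cw + n_ccw == 0:
        raise UndefinedBiasError("window contains no non-pause frames")
    if window is None:
        window = (float(ds.t[0]), float(ds.t[-1]))
    speed = np.abs(ds.signed_speed_hz[m][s != PAUSE])
    return MotorSummary(
        cw_bias=n_cw / (n_cw + n_ccw),
        reversal_rate=count_reversals(ds, window),
        mean_speed=float(np.mean(speed)) if len(speed) else 0.0,
        window=(float(window[0]), float(window[1])),
        n_frames_cw=n_cw, n_frames_ccw=n_ccw, n_frames_pause=n_pause)


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    metric: str
    equal_var: bool


def compare_pre_post(pre: list[MotorSummary], post: list[MotorSummary],
                     metric: str = "reversal_rate",
                     equal_var: bool = True) -> TTestResult:
    """Two-sample Student's t-test on a motor-summary metric.

    ``equal_var=True`` is the classic Student's test; pass False for
    Welch's correction.  Reports group means with their SEM.
    """
    if len(pre) < 2 or len(post) < 2:
        raise InsufficientReplicatesError("need >= 2 motors per group")
    a = np.array([getattr(s, metric) for s in pre], dtype=float)
    b = np.array([getattr(s, metric) for s in post], dtype=float)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        # degenerate but well-defined: identical constant groups
        res = None
        stat, pval, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        stat, pval = float(res.statistic), float(res.pvalue)
        df = float(len(a) + len(b) - 2) if equal_var else float(res.df)
    return TTestResult(
        statistic=stat, pvalue=pval, df=df,
        mean_a=float(np.mean(a)), sem_a=float(stats.sem(a)),
        mean_b=float(np.mean(b)), sem_b=float(stats.sem(b)),
        metric=metric, equal_var=equal_var)
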