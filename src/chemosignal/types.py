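"""Shared domain containers.

Conventions used throughout the package:

* Time is in seconds, positions in micrometres, rotation speed in Hz
  (bead revolutions per second), intensities in camera counts.
* Rotation sign follows the bead-assay convention: clockwise (CW)
  rotation is *positive*, counterclockwise (CCW) negative.  In standard
  mathematical axes (y up) CCW corresponds to increasing angle, so the
  signed speed is the negated angular velocity over 2*pi.
* Direction states are coded as integers: ``CW = +1``, ``CCW = -1``,
  ``PAUSE = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, UndefinedBiasError

CW: int = 1
CCW: int = -1
PAUSE: int = 0

STATE_NAMES = {CW: "CW", CCW: "CCW", PAUSE: "PAUSE"}


# ---------------------------------------------------------------------------
# bead assay
# ---------------------------------------------------------------------------

@dataclass
class MotorTrace:
    """Timestamped bead positions from one flagellar-motor recording.

    ``t`` must be strictly increasing and uniformly spaced at ``fps``.
    """

    t: np.ndarray          # s
    x: np.ndarray          # um
    y: np.ndarray          # um
    fps: float             # frames / s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidArgumentError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InvalidArgumentError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fps)) > 1e-6 / self.fps + 1e-9:
                raise InvalidArgumentError("time must be uniform at fps")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


@dataclass
class DirectionSeries:
    """Per-frame rotation-state labels and signed speed.

    ``state`` holds the integer codes ``CW``/``CCW``/``PAUSE``;
    ``signed_speed_hz`` is positive for CW frames.
    """

    t: np.ndarray                  # s
    state: np.ndarray              # int8 codes
    signed_speed_hz: np.ndarray    # Hz, CW positive

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        self.signed_speed_hz = np.asarray(self.signed_speed_hz, dtype=float)
        if not (len(self.t) == len(self.state) == len(self.signed_speed_hz)):
            raise InvalidArgumentError("t, state, signed_speed must align")

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        if window is None:
            return np.ones(len(self.t), dtype=bool)
        t0, t1 = window
        return (self.t >= t0) & (self.t < t1)


@dataclass
class MotorSummary:
    """Per-window summary statistics of one motor recording."""

    cw_bias: float                  # fraction in [0, 1]
    reversal_rate: float            # reversals / min
    mean_speed: float               # Hz (mean |signed speed| over non-pause)
    window: tuple[float, float]     # s
    n_frames_cw: int
    n_frames_ccw: int
    n_frames_pause: int

    def __post_init__(self):
        total = self.n_frames_cw + self.n_frames_ccw
        if total == 0:
            raise UndefinedBiasError("window contains no non-pause frames")
        expected = self.n_frames_cw / total
        if abs(self.cw_bias - expected) > 1e-12:
            raise InvalidArgumentError("cw_bias inconsistent with frame counts")


# ---------------------------------------------------------------------------
# FRET assay
# ---------------------------------------------------------------------------

@dataclass
class StimulusEvent:
    time: float             # s
    kind: str               # "add" | "remove"
    ligand: str = ""
    concentration: str = ""

    def __post_init__(self):
        if self.kind not in ("add", "remove"):
            raise InvalidArgumentError(f"unknown stimulus kind {self.kind!r}")


@dataclass
class SaturatingWindow:
    t_start: float
    t_end: float
    expected_extreme: str   # "min" | "max"

    def __post_init__(self):
        if self.expected_extreme not in ("min", "max"):
            raise InvalidArgumentError(
                f"expected_extreme must be 'min' or 'max', got "
                f"{self.expected_extreme!r}")
        if self.t_end <= self.t_start:
            raise InvalidArgumentError("saturating window must have t_end > t_start")


@dataclass
class StimulusSchedule:
    """Stimulus additions/removals plus the saturating calibration windows."""

    events: list[StimulusEvent] = field(default_factory=list)
    saturating_windows: list[SaturatingWindow] = field(default_factory=list)

    def __post_init__(self):
        wins = sorted(self.saturating_windows, key=lambda w: w.t_start)
        for a, b in zip(wins, wins[1:]):
            if b.t_start < a.t_end:
                raise InvalidArgumentError("saturating windows overlap")

    def windows(self, extreme: str) -> list[SaturatingWindow]:
        return [w for w in self.saturating_windows if w.expected_extreme == extreme]

    def first_event_time(self, kind: str | None = None) -> float | None:
        times = [e.time for e in self.events if kind is None or e.kind == kind]
        return min(times) if times else None


@dataclass
class FretExperiment:
    """Three-channel per-cell intensity time series.

    ``idd``: donor emission, donor excitation; ``ida``: acceptor emission,
    donor excitation (sensitized); ``iaa``: acceptor emission, acceptor
    excitation.
    """

    t: np.ndarray
    idd: np.ndarray
    ida: np.ndarray
    iaa: np.ndarray
    schedule: StimulusSchedule = field(default_factory=StimulusSchedule)
    cell_id: str = "cell"
    bleach_corrected: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.idd = np.asarray(self.idd, dtype=float)
        self.ida = np.asarray(self.ida, dtype=float)
        self.iaa = np.asarray(self.iaa, dtype=float)
        n = len(self.t)
        if not (len(self.idd) == len(self.ida) == len(self.iaa) == n):
            raise InvalidArgumentError("channel series must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")


@dataclass
class EfretConstants:
    """Optical constants of the three-cube E-FRET equation.

    ``a`` — acceptor direct-excitation bleed-through (IDA counts per IAA
    count with no donor); ``d`` — donor emission bleed-through into the
    FRET channel; ``G`` — gauge factor converting lost donor counts into
    sensitized-emission counts.
    """

    a: float
    d: float
    G: float
    g_provenance: str = "config"

    def __post_init__(self):
        if self.a < 0 or self.d < 0:
            raise InvalidArgumentError("a and d must be >= 0")
        if self.G <= self.d:
            raise InvalidArgumentError("require G > d (denominator can vanish otherwise)")


@dataclass
class KinaseActivitySeries:
    """Normalized kinase activity, 0 = kinase-OFF, 1 = kinase-ON."""

    t: np.ndarray
    activity: np.ndarray            # clipped to [0, 1]
    baseline: float | None = None
    adaptation_time: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.t) != len(self.activity):
            raise InvalidArgumentError("t and activity must align")


# ---------------------------------------------------------------------------
# swarm z-tracking
# ---------------------------------------------------------------------------

@dataclass
class RingCalibration:
    """Linear map between diffraction-ring diameter (px) and height z (um)."""

    d0: float               # px, in-focus diameter
    slope: float            # px / um
    z_range: tuple[float, float] = (0.0, 150.0)
    noise_sd: float = 0.0   # px, diameter measurement noise

    def __post_init__(self):
        if self.slope <= 0:
            raise InvalidArgumentError("calibration slope must be > 0")
        if self.z_range[1] <= self.z_range[0]:
            raise InvalidArgumentError("z_range must be increasing")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    def diameter_at(self, z: float | np.ndarray) -> float | np.ndarray:
        return self.d0 + self.slope * np.asarray(z, dtype=float)


@dataclass
class RingObservation:
    """One cell's diffraction-ring diameter and (optionally) inferred z."""

    diameter_px: float
    x_um: float = 0.0
    z_um: float | None = None          # inferred height
    z_true_um: float | None = None     # ground truth when synthetic
    condition: str = ""
    replicate: str = ""
    out_of_range: bool = False

    def __post_init__(self):
        if self.diameter_px < 0:
            raise InvalidArgumentError("diameter must be >= 0")


def states_to_names(state: np.ndarray) -> list[str]:
    return [STATE_NAMES[int(s)] for s in np.asarray(state)]


def names_to_states(names: Sequence[str]) -> np.ndarray:
    lookup = {v: k for k, v in STATE_NAMES.items()}
    try:
        return np.array([lookup[n] for n in names], dtype=np.int8)
    except KeyError as exc:
        raise InvalidArgumentError(f"unknown state label {exc.args[0]!r}") from exc
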