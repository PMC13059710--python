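"""Named experimental-condition presets.

Each preset encodes only observable statistics reported for the
corresponding condition — baseline reversal rate 39.07/min, repellent
(peroxide) reversal rate 64.53/min, ~1 min adaptation, the ~6 min onset
of the kanamycin repellent phase within a 10-min window — mapped onto
generator parameters through the exact stationary relations of the
two-state switching model:

    CW bias      beta = k1 / (k1 + k2)
    reversal rate R   = 2 k1 k2 / (k1 + k2)      (events/s)

so k1 + k2 = R / (2 beta (1 - beta)), k1 = beta (k1 + k2).  Baseline CW
bias is not printed numerically ("predominantly CCW with frequent CW
reversals"); 0.2 is used for the baseline and 0.35 under repellent,
typical bead-assay values for pre- and post-repellent E. coli motors.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .synthetic import BleachModel, KinaseStepModel, SwitchingModel
from .types import (
    EfretConstants,
    RingCalibration,
    SaturatingWindow,
    StimulusEvent,
    StimulusSchedule,
)

__all__ = [
    "rates_from_observables",
    "relaxing_rate_map",
    "motor_preset",
    "fret_preset",
    "ring_preset",
    "MOTOR_PRESETS",
    "DEFAULT_RING_CALIBRATION",
    "DEFAULT_EFRET_CONSTANTS",
    "DEFAULT_KINASE_MODEL",
    "DEFAULT_DONOR_BLEACH",
    "DEFAULT_ACCEPTOR_BLEACH",
]


def rates_from_observables(reversals_per_min: float,
                           cw_bias: float) -> tuple[float, float]:
    """Invert the stationary relations to (k_ccw_to_cw, k_cw_to_ccw)."""
    if not 0.0 < cw_bias < 1.0:
        raise InvalidArgumentError("cw_bias must be in (0, 1)")
    if reversals_per_min <= 0:
        raise InvalidArgumentError("reversal rate must be > 0")
    rate_s = reversals_per_min / 60.0
    total = rate_s / (2.0 * cw_bias * (1.0 - cw_bias))
    return cw_bias * total, (1.0 - cw_bias) * total


def relaxing_rate_map(t_on: float, duration: float,
                      stim_rates: tuple[float, float],
                      base_rates: tuple[float, float],
                      tau: float = 60.0,
                      step: float = 1.0) -> list[tuple[float, float, float, float]]:
    """Piecewise-constant approximation of switching rates that jump at
    ``t_on`` and relax exponentially back to baseline with time constant
    ``tau`` (adaptation), sampled at ``step``-second segments."""
    out = []
    t = t_on
    while t < duration:
        t1 = min(t + step, duration)
        decay = np.exp(-((t + t1) / 2.0 - t_on) / tau)
        k1 = base_rates[0] + (stim_rates[0] - base_rates[0]) * decay
        k2 = base_rates[1] + (stim_rates[1] - base_rates[1]) * decay
        out.append((t, t1, float(k1), float(k2)))
        t = t1
    return out


#: observable statistics each motor preset encodes
_MOTOR_OBSERVABLES = {
    "wt_baseline": {"reversals_per_min": 39.07, "cw_bias": 0.20},
    # baseline statistics; the repellent response lives in the rate map
    "wt_peroxide": {"reversals_per_min": 39.07, "cw_bias": 0.20},
    "aer_null": {"reversals_per_min": 39.07, "cw_bias": 0.20},
    "kanamycin_biphasic": {"reversals_per_min": 39.07, "cw_bias": 0.20},
}

MOTOR_PRESETS = tuple(_MOTOR_OBSERVABLES)


def motor_preset(name: str, stimulus_time: float | None = None,
                 duration: float | None = None,
                 adaptation_tau: float = 60.0,
                 speed_hz: float = 10.0) -> SwitchingModel:
    """Build the switching model for a named condition.

    ``wt_baseline`` — stationary baseline statistics.
    ``wt_peroxide`` — baseline until ``stimulus_time`` (default 60 s),
      then repellent statistics relaxing back with ``adaptation_tau``.
    ``aer_null`` — identical rates before and after the stimulus
      (no-effect control for type-I calibration).
    ``kanamycin_biphasic`` — attractant phase (reversals halved) from
      the stimulus until ~6 min later, then the repellent statistics,
      within the 10-min antibiotic observation window.
    """
    if name not in _MOTOR_OBSERVABLES:
        raise InvalidArgumentError(
            f"unknown preset {name!r}; choose from {MOTOR_PRESETS}")
    obs = _MOTOR_OBSERVABLES[name]
    base = rates_from_observables(obs["reversals_per_min"], obs["cw_bias"])
    rate_map: list[tuple[float, float, float, float]] = []
    if name == "wt_peroxide":
        t_on = 60.0 if stimulus_time is None else stimulus_time
        dur = 120.0 if duration is None else duration
        stim = rates_from_observables(64.53, 0.35)
        rate_map = relaxing_rate_map(t_on, dur, stim, base, tau=adaptation_tau)
    elif name == "kanamycin_biphasic":
        t_on = 60.0 if stimulus_time is None else stimulus_time
        dur = (t_on + 600.0) if duration is None else duration
        attract = rates_from_observables(39.07 / 2.0, 0.10)
        repel = rates_from_observables(64.53, 0.35)
        t_repel = min(t_on + 360.0, dur)   # repellent phase from ~6 min
        rate_map = [(t_on, t_repel, *attract), (t_repel, dur, *repel)]
    return SwitchingModel(rate_ccw_to_cw=base[0], rate_cw_to_ccw=base[1],
                          speed_hz=speed_hz, stimulus_rate_map=rate_map)


DEFAULT_EFRET_CONSTANTS = EfretConstants(a=0.08, d=0.12, G=2.0)
DEFAULT_KINASE_MODEL = KinaseStepModel()
DEFAULT_DONOR_BLEACH = BleachModel(amp1=0.3, tau1=100.0, tau2=1000.0)
DEFAULT_ACCEPTOR_BLEACH = BleachModel(amp1=0.3, tau1=150.0, tau2=2000.0)


def fret_preset(duration: float = 240.0,
                stimulus_time: float = 45.0,
                removal_time: float = 150.0) -> StimulusSchedule:
    """Step stimulus with saturating calibration windows at both ends.

    Mirrors the standard protocol: a saturating kinase-OFF window at the
    start, the test stimulus step (add/remove), and a saturating
    kinase-ON window at the end of the recording.
    """
    return StimulusSchedule(
        events=[StimulusEvent(time=stimulus_time, kind="add",
                              ligand="H2O2", concentration="1 mM"),
                StimulusEvent(time=removal_time, kind="remove",
                              ligand="H2O2", concentration="1 mM")],
        saturating_windows=[
            SaturatingWindow(0.0, 15.0, "min"),
            SaturatingWindow(duration - 15.0, duration, "max")])


DEFAULT_RING_CALIBRATION = RingCalibration(d0=6.0, slope=0.8,
                                           z_range=(0.0, 150.0),
                                           noise_sd=0.3)


def ring_preset(condition: str, n: int, rng: np.random.Generator,
                z_max: float = 150.0) -> np.ndarray:
    """Ground-truth z distributions for the swarm scenarios.

    ``wt_kanamycin`` — cells avoid the antibiotic-rich agar surface:
    truncated normal centered high in the colony (mean 110 um, SD 25).
    ``aer_null`` — no avoidance: uniform over the colony height.
    """
    if condition == "wt_kanamycin":
        z = rng.normal(110.0, 25.0, size=2 * n)
        z = z[(z >= 0.0) & (z <= z_max)][:n]
        while len(z) < n:
            extra = rng.normal(110.0, 25.0, size=n)
            z = np.concatenate([z, extra[(extra >= 0) & (extra <= z_max)]])[:n]
        return z
    if condition == "aer_null":
        return rng.uniform(0.0, z_max, size=n)
    raise InvalidArgumentError(f"unknown ring preset {condition!r}")
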