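"""Defocused diffraction-ring 3D localization within swarm colonies.

A fluorescent cell above the focal plane produces an out-of-focus
diffraction ring whose diameter grows with its height z; with a linear
diameter-vs-z calibration, measuring the ring diameter localizes the
cell vertically through the ~150-um colony.  This module estimates ring
diameters from single-ring images by radial intensity profiling, maps
diameters to z, and compares vertical distributions across conditions
with a paired Student's t-test on per-replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DetectionError, InvalidArgumentError, PairingError
from .types import RingCalibration, RingObservation

__all__ = [
    "RingEstimate",
    "estimate_ring_diameter",
    "diameter_to_z",
    "observations_to_frame",
    "summarize_colony",
]

#: diameters below this radius peak (px) are treated as an in-focus spot
FOCUSED_SPOT_RADIUS = 1.0


@dataclass
class RingEstimate:
    diameter_px: float
    quality: float          # peak prominence / background SD
    center: tuple[float, float]
    focused_spot: bool = False


def _radial_profile(image: np.ndarray, center: tuple[float, float],
                    bin_width: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity vs radius by annular binning with linear
    interpolation of each pixel between its two nearest bins."""
    cy, cx = center
    yy, xx = np.indices(image.shape)
    r = np.hypot(yy - cy, xx - cx).ravel()
    v = image.ravel()
    pos = r / bin_width
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    nbins = int(np.max(i0)) + 2
    wsum = (np.bincount(i0, weights=(1 - frac) * v, minlength=nbins)
            + np.bincount(i0 + 1, weights=frac * v, minlength=nbins))
    w = (np.bincount(i0, weights=1 - frac, minlength=nbins)
         + np.bincount(i0 + 1, weights=frac, minlength=nbins))
    with np.errstate(invalid="ignore"):
        prof = np.where(w > 0, wsum / np.where(w > 0, w, 1), np.nan)
    radii = np.arange(nbins) * bin_width
    return radii, prof


def estimate_ring_diameter(image: np.ndarray,
                           center_guess: tuple[float, float] | None = None,
                           bin_width: float = 0.25,
                           min_quality: float = 3.0) -> RingEstimate:
    """Estimate a single ring's diameter by radial-profile peak finding.

    The center is refined by the intensity centroid of the
    background-subtracted image; the radial profile (``bin_width`` px
    annuli) is peak-located with quadratic sub-bin interpolation.
    Quality is peak prominence over the background SD (estimated from
    the image border); below ``min_quality`` a DetectionError is raised.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 8:
        raise InvalidArgumentError("image must be 2-D and at least 8x8")
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    bg_mean = float(np.median(border))
    bg_sd = float(np.std(border))

    weights = np.clip(image - bg_mean, 0.0, None)
    total = float(weights.sum())
    if total <= 0:
        raise DetectionError("image has no intensity above background")
    yy, xx = np.indices(image.shape)
    if center_guess is not None:
        cy, cx = center_guess
    else:
        cy = float((weights * yy).sum() / total)
        cx = float((weights * xx).sum() / total)

    radii, prof = _radial_profile(image - bg_mean, (cy, cx), bin_width)
    # ignore the outermost bins, which are sampled only in the corners
    usable = int((min(image.shape) / 2.0) / bin_width)
    prof = prof[:usable]
    radii = radii[:usable]
    finite = np.isfinite(prof)
    if not np.any(finite):
        raise DetectionError("empty radial profile")
    i_pk = int(np.nanargmax(prof))
    peak = float(prof[i_pk])
    prominence = peak - float(np.nanmedian(prof))
    quality = prominence / bg_sd if bg_sd > 0 else np.inf
    if quality < min_quality:
        raise DetectionError(
            f"no prominent ring (quality {quality:.2f} < {min_quality})")

    r_pk = radii[i_pk]
    if 0 < i_pk < len(prof) - 1 and np.isfinite(prof[i_pk - 1]) \
            and np.isfinite(prof[i_pk + 1]):
        y0, y1, y2 = prof[i_pk - 1], prof[i_pk], prof[i_pk + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            r_pk = r_pk + 0.5 * (y0 - y2) / denom * bin_width
    focused = r_pk < FOCUSED_SPOT_RADIUS
    return RingEstimate(diameter_px=float(max(2.0 * r_pk, 0.0)),
                        quality=float(quality), center=(cy, cx),
                        focused_spot=bool(focused))


def diameter_to_z(diameter: float | np.ndarray,
                  calibration: RingCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Invert the linear diameter-z calibration.

    Returns ``(z, out_of_range)``; z is clamped to the calibration range
    and the flag marks clamped values, so census totals are conserved.
    """
    d = np.asarray(diameter, dtype=float)
    z = (d - calibration.d0) / calibration.slope
    z_lo, z_hi = calibration.z_range
    out = (z < z_lo) | (z > z_hi)
    return np.clip(z, z_lo, z_hi), out


def observations_to_frame(observations: list[RingObservation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "x_um": o.x_um, "diameter_px": o.diameter_px, "z_um": o.z_um,
        "z_true_um": o.z_true_um, "condition": o.condition,
        "replicate": o.replicate, "out_of_range": o.out_of_range,
    } for o in observations])


def summarize_colony(observations: pd.DataFrame | list[RingObservation],
                     control: str,
                     calibration: RingCalibration | None = None,
                     bottom_um: float = 20.0) -> dict:
    """Per-condition z statistics plus paired t-tests against a control.

    Input rows need ``z_um`` (or ``diameter_px`` with a calibration),
    ``condition`` and ``replicate``.  The paired test compares
    per-replicate mean z between each condition and the control over
    replicates present in both; the summary also reports the fraction of
    cells within ``bottom_um`` of the agar surface.
    """
    if not isinstance(observations, pd.DataFrame):
        observations = observations_to_frame(observations)
    df = observations.copy()
    if df["z_um"].isna().all() if "z_um" in df else True:
        if calibration is None:
            raise InvalidArgumentError(
                "observations carry no z; supply a calibration")
        z, out = diameter_to_z(df["diameter_px"].to_numpy(), calibration)
        df["z_um"] = z
        df["out_of_range"] = out
    conditions = sorted(df["condition"].unique())
    if control not in conditions:
        raise InvalidArgumentError(f"control condition {control!r} not present")

    summary: dict = {"control": control, "conditions": {}, "tests": {}}
    for cond, sub in df.groupby("condition"):
        z = sub["z_um"].to_numpy(dtype=float)
        summary["conditions"][str(cond)] = {
            "n": {"value": int(len(z)), "units": "cells"},
            "mean_z": {"value": float(np.mean(z)), "units": "um"},
            "median_z": {"value": float(np.median(z)), "units": "um"},
            "q25_z": {"value": float(np.percentile(z, 25)), "units": "um"},
            "q75_z": {"value": float(np.percentile(z, 75)), "units": "um"},
            "bottom_fraction": {
                "value": float(np.mean(z <= bottom_um)), "units": "fraction",
                "definition": f"z <= {bottom_um} um"},
        }

    ctrl_means = df[df["condition"] == control].groupby("replicate")["z_um"].mean()
    for cond in conditions:
        if cond == control:
            continue
        cond_means = df[df["condition"] == cond].groupby("replicate")["z_um"].mean()
        shared = sorted(set(ctrl_means.index) & set(cond_means.index))
        if len(shared) < 2:
            raise PairingError(
                f"condition {cond!r} and control share {len(shared)} "
                "replicate(s); need >= 2 paired replicates")
        a = cond_means.loc[shared].to_numpy()
        b = ctrl_means.loc[shared].to_numpy()
        diffs = a - b
        if np.allclose(diffs, 0.0):
            # degenerate paired test: no difference anywhere
            stat, pval = 0.0, 1.0
        else:
            res = stats.ttest_rel(a, b)
            stat, pval = float(res.statistic), float(res.pvalue)
        summary["tests"][str(cond)] = {
            "statistic": {"value": stat, "units": "t"},
            "pvalue": {"value": pval, "units": "probability"},
            "df": {"value": int(len(shared) - 1), "units": "degrees of freedom"},
            "n_pairs": {"value": int(len(shared)), "units": "replicates"},
            "mean_difference": {"value": float(np.mean(a - b)), "units": "um"},
        }
    return summary
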