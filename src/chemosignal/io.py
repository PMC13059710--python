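"""File formats, configuration and the batch pipeline.

CSV dialect everywhere: comma-separated, UTF-8, '.' decimal, mandatory
header row.  Trace schemas:

* motor:  ``time_s,x_um,y_um``  (or ``time_s,angle_rad``)
* fret:   ``time_s,IDD,IDA,IAA``
* rings:  ``x_um,diameter_px,condition,replicate`` (optional ``z_um``)

Every simulated trace gets a JSON sidecar (``<name>.truth.json``)
holding the generator parameters and ground truth; every pipeline run
writes a resolved-config copy next to its outputs.  All numeric values
in JSON summaries are ``{"value": ..., "units": ...}`` objects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import motor as motor_mod
from .errors import InvalidArgumentError, SchemaError
from .synthetic import MotorSimulation
from .types import (
    FretExperiment,
    MotorTrace,
    RingCalibration,
    RingObservation,
    SaturatingWindow,
    StimulusEvent,
    StimulusSchedule,
)

__all__ = [
    "read_motor_trace", "write_motor_trace",
    "read_fret_trace", "write_fret_trace",
    "read_ring_observations", "write_ring_observations",
    "read_calibration", "write_calibration",
    "read_schedule", "write_schedule",
    "write_motor_sidecar",
    "RunConfig", "run_pipeline",
]

_FLOAT_FMT = "%.17g"   # lossless round trip for finite doubles


def _read_csv(path, required: set[str], optional: set[str] = frozenset()):
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) "
                          f"{', '.join(sorted(missing))}")
    unknown = set(df.columns) - required - optional
    if unknown:
        raise SchemaError(f"{path.name}: unknown column(s) "
                          f"{', '.join(sorted(unknown))}")
    return df


def _check_time(t: np.ndarray, name: str):
    bad = np.flatnonzero(~np.isfinite(t))
    if len(bad):
        raise SchemaError(f"{name}: non-finite time", row=int(bad[0]))
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        raise SchemaError(f"{name}: time not strictly increasing "
                          "(duplicate or reversed timestamp)", row=int(bad[0] + 1))


def read_motor_trace(path) -> MotorTrace:
    """Read a bead trace; fps is inferred from the time column.

    Accepts either ``time_s,x_um,y_um`` or pre-extracted angles
    ``time_s,angle_rad`` (converted to unit-radius positions).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if {"time_s", "angle_rad"} <= cols:
        t = df["time_s"].to_numpy(dtype=float)
        _check_time(t, path.name)
        theta = df["angle_rad"].to_numpy(dtype=float)
        x, y = np.cos(theta), np.sin(theta)
    else:
        missing = {"time_s", "x_um", "y_um"} - cols
        if missing:
            raise SchemaError(f"{path.name}: missing column(s) "
                              f"{', '.join(sorted(missing))}")
        t = df["time_s"].to_numpy(dtype=float)
        _check_time(t, path.name)
        x = df["x_um"].to_numpy(dtype=float)
        y = df["y_um"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path.name}: need at least 2 frames")
    dt = np.diff(t)
    if np.max(dt) - np.min(dt) > 1e-6 * np.mean(dt):
        raise SchemaError(f"{path.name}: non-uniform sampling interval")
    fps = 1.0 / float(np.mean(dt))
    return MotorTrace(t=t, x=x, y=y, fps=fps, metadata={"source": str(path)})


def write_motor_trace(trace: MotorTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.t, "x_um": trace.x, "y_um": trace.y}
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_motor_sidecar(sim: MotorSimulation, trace_path) -> Path:
    """Ground truth + parameters for a simulated motor trace."""
    path = Path(trace_path).with_suffix(".truth.json")
    model = sim.model
    payload = {
        "model": {
            "rate_ccw_to_cw": {"value": model.rate_ccw_to_cw, "units": "1/s"},
            "rate_cw_to_ccw": {"value": model.rate_cw_to_ccw, "units": "1/s"},
            "speed_hz": {"value": model.speed_hz, "units": "Hz"},
            "pause_prob_per_switch": {"value": model.pause_prob_per_switch,
                                      "units": "fraction"},
            "stimulus_rate_map": model.stimulus_rate_map,
        },
        "jump_path": {
            "times_s": sim.path.times.tolist(),
            "states": sim.path.states.tolist(),
            "t_end_s": sim.path.t_end,
        },
        "n_switches": {"value": sim.path.n_switches(), "units": "events"},
    }
    path.write_text(json.dumps(payload))
    return path


def read_fret_trace(path, schedule: StimulusSchedule | None = None,
                    cell_id: str | None = None) -> FretExperiment:
    path = Path(path)
    df = _read_csv(path, {"time_s", "IDD", "IDA", "IAA"})
    t = df["time_s"].to_numpy(dtype=float)
    _check_time(t, path.name)
    for col in ("IDD", "IDA", "IAA"):
        v = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(v < 0)
        if len(bad):
            raise SchemaError(f"{path.name}: negative intensity in {col}",
                              row=int(bad[0]))
    return FretExperiment(t=t, idd=df["IDD"].to_numpy(float),
                          ida=df["IDA"].to_numpy(float),
                          iaa=df["IAA"].to_numpy(float),
                          schedule=schedule or StimulusSchedule(),
                          cell_id=cell_id or path.stem)


def write_fret_trace(exp: FretExperiment, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": exp.t, "IDD": exp.idd, "IDA": exp.ida,
                  "IAA": exp.iaa}).to_csv(path, index=False,
                                          float_format=_FLOAT_FMT)
    return path


def read_ring_observations(path) -> pd.DataFrame:
    df = _read_csv(Path(path), {"x_um", "diameter_px", "condition", "replicate"},
                   optional={"z_um", "z_true_um", "out_of_range"})
    bad = np.flatnonzero(df["diameter_px"].to_numpy(dtype=float) < 0)
    if len(bad):
        raise SchemaError(f"{Path(path).name}: negative diameter",
                          row=int(bad[0]))
    if "z_um" not in df.columns:
        df["z_um"] = np.nan
    df["replicate"] = df["replicate"].astype(str)
    return df


def write_ring_observations(obs: pd.DataFrame | list[RingObservation],
                            path) -> Path:
    from .ztrack import observations_to_frame
    if not isinstance(obs, pd.DataFrame):
        obs = observations_to_frame(obs)
    path = Path(path)
    obs.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def _load_yaml_mapping(path, allowed: set[str], what: str) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"{what}: expected a YAML mapping")
    unknown = set(data) - allowed
    if unknown:
        raise SchemaError(f"{what}: unknown key(s) {', '.join(sorted(unknown))}")
    return data


def read_calibration(path) -> RingCalibration:
    data = _load_yaml_mapping(path, {"d0", "slope", "z_max", "noise_sd"},
                              "calibration")
    return RingCalibration(d0=float(data["d0"]), slope=float(data["slope"]),
                           z_range=(0.0, float(data.get("z_max", 150.0))),
                           noise_sd=float(data.get("noise_sd", 0.0)))


def write_calibration(calib: RingCalibration, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({
        "d0": calib.d0, "slope": calib.slope,
        "z_max": calib.z_range[1], "noise_sd": calib.noise_sd}))
    return path


def read_schedule(path) -> StimulusSchedule:
    data = _load_yaml_mapping(path, {"events", "saturating_windows"}, "schedule")
    events = [StimulusEvent(time=float(e["time"]), kind=str(e["kind"]),
                            ligand=str(e.get("ligand", "")),
                            concentration=str(e.get("concentration", "")))
              for e in data.get("events", [])]
    wins = [SaturatingWindow(float(w["t_start"]), float(w["t_end"]),
                             str(w["expected_extreme"]))
            for w in data.get("saturating_windows", [])]
    return StimulusSchedule(events=events, saturating_windows=wins)


def write_schedule(schedule: StimulusSchedule, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump({
        "events": [{"time": e.time, "kind": e.kind, "ligand": e.ligand,
                    "concentration": e.concentration} for e in schedule.events],
        "saturating_windows": [{"t_start": w.t_start, "t_end": w.t_end,
                                "expected_extreme": w.expected_extreme}
                               for w in schedule.saturating_windows]}))
    return path


# ---------------------------------------------------------------------------
# batch pipeline
# ---------------------------------------------------------------------------

_RUNCONFIG_KEYS = {"seed", "module", "preset", "inputs", "out_dir",
                   "stimulus_time", "duration", "fps", "n_motors",
                   "smooth_window", "overrides"}


@dataclass
class RunConfig:
    """Resolved configuration of one batch run."""

    seed: int = 0
    module: str = "motor"
    preset: str | None = None
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "results"
    stimulus_time: float = 60.0
    duration: float = 120.0
    fps: float = 250.0
    n_motors: int = 10
    smooth_window: float = 30.0
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = _load_yaml_mapping(path, _RUNCONFIG_KEYS, "run config")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path


def _q(value, units):
    return {"value": value, "units": units}


def run_pipeline(config: RunConfig) -> dict:
    """Simulate-and-analyze batch driver for the motor assay.

    Generates ``n_motors`` traces from the named preset, analyzes pre-
    vs post-stimulus windows, and writes a JSON summary (plus the
    resolved config) under ``out_dir``.  Deterministic for a fixed seed.
    """
    from . import presets as presets_mod

    if config.module != "motor":
        raise InvalidArgumentError(
            "run_pipeline currently drives the motor assay; use the module "
            "APIs or the analysis scripts for fret/ztrack batches")
    if not config.preset:
        raise InvalidArgumentError("config.preset is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    model = presets_mod.motor_preset(
        config.preset, stimulus_time=config.stimulus_time,
        duration=config.duration,
        **{k: v for k, v in config.overrides.items()
           if k in ("adaptation_tau", "speed_hz")})
    rng = np.random.default_rng(config.seed)
    pre_summaries, post_summaries = [], []
    for i in range(config.n_motors):
        from .synthetic import simulate_motor_trace
        sim = simulate_motor_trace(model, duration=config.duration,
                                   fps=config.fps, seed=rng)
        rot = motor_mod.estimate_rotation(sim.trace)
        ds = motor_mod.classify_direction(rot)
        pre_summaries.append(
            motor_mod.summarize_window(ds, (0.0, config.stimulus_time)))
        post_summaries.append(
            motor_mod.summarize_window(ds, (config.stimulus_time,
                                            config.duration)))
    test = motor_mod.compare_pre_post(pre_summaries, post_summaries,
                                      metric="reversal_rate")
    summary = {
        "preset": config.preset,
        "seed": config.seed,
        "n_motors": _q(config.n_motors, "motors"),
        "pre": {
            "mean_reversal_rate": _q(test.mean_a, "reversals/min"),
            "sem_reversal_rate": _q(test.sem_a, "reversals/min"),
            "mean_cw_bias": _q(float(np.mean([s.cw_bias for s in pre_summaries])),
                               "fraction"),
        },
        "post": {
            "mean_reversal_rate": _q(test.mean_b, "reversals/min"),
            "sem_reversal_rate": _q(test.sem_b, "reversals/min"),
            "mean_cw_bias": _q(float(np.mean([s.cw_bias for s in post_summaries])),
                               "fraction"),
        },
        "t_test": {
            "statistic": _q(test.statistic, "t"),
            "pvalue": _q(test.pvalue, "probability"),
            "df": _q(test.df, "degrees of freedom"),
        },
    }
    (out / "motor_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
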