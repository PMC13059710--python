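#!/usr/bin/env python
"""Analyze the simulated bead-assay cohorts: repellent response to peroxide.

Reads the traces written by 01_simulate_cohorts.py, estimates rotation,
classifies direction, and compares reversal rates before and after the
stimulus within each cohort.  The baseline cohort should show no pre/post
change; the peroxide cohort should show the jump from ~39 to ~65
reversals/min.  Writes results/motor_response.json.
"""

import json
from pathlib import Path

import numpy as np

from chemosignal import io as cio
from chemosignal import motor

ROOT = Path(__file__).resolve().parents[1] / "results"
STIM_TIME = 60.0


def analyze_cohort(d: Path) -> dict:
    pre, post = [], []
    for path in sorted(d.glob("motor_*.csv")):
        trace = cio.read_motor_trace(path)
        ds = motor.classify_direction(motor.estimate_rotation(trace))
        pre.append(motor.summarize_window(ds, (0.0, STIM_TIME)))
        post.append(motor.summarize_window(ds, (STIM_TIME, trace.t[-1])))
    test = motor.compare_pre_post(pre, post, metric="reversal_rate")
    return {
        "n_motors": {"value": len(pre), "units": "motors"},
        "pre_reversal_rate": {"value": test.mean_a, "sem": test.sem_a,
                              "units": "reversals/min"},
        "post_reversal_rate": {"value": test.mean_b, "sem": test.sem_b,
                               "units": "reversals/min"},
        "pre_cw_bias": {"value": float(np.mean([s.cw_bias for s in pre])),
                        "units": "fraction"},
        "post_cw_bias": {"value": float(np.mean([s.cw_bias for s in post])),
                         "units": "fraction"},
        "t_statistic": {"value": test.statistic, "units": "t"},
        "pvalue": {"value": test.pvalue, "units": "probability"},
    }


def main() -> None:
    sim_root = ROOT.parent / "scratch" / "sim" / "motor"
    if not sim_root.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = {}
    for preset_dir in sorted(sim_root.iterdir()):
        res = analyze_cohort(preset_dir)
        out[preset_dir.name] = res
        print(f"{preset_dir.name}: "
              f"pre {res['pre_reversal_rate']['value']:.1f} rev/min, "
              f"post {res['post_reversal_rate']['value']:.1f} rev/min, "
              f"p = {res['pvalue']['value']:.2g}")
    (ROOT / "motor_response.json").write_text(
        json.dumps(out, indent=2, sort_keys=True))
    print(f"wrote {ROOT / 'motor_response.json'}")


if __name__ == "__main__":
    main()
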