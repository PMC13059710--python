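#!/usr/bin/env python
"""Generate the synthetic study cohorts used by the downstream analyses.

Writes bead-assay traces (with ground-truth sidecars) for the baseline
and peroxide-response presets, a set of three-channel FRET recordings
under the default step-stimulus protocol, and ring-diameter observation
tables for the two swarm scenarios, all under results/sim/.
"""

from pathlib import Path

import numpy as np

from chemosignal import io as cio
from chemosignal import presets, synthetic

SEED = 12345
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"


def main() -> None:
    rng = np.random.default_rng(SEED)

    # --- motor cohorts: 60 s baseline, 60 s post-stimulus, 250 fps ---
    for preset in ("wt_baseline", "wt_peroxide"):
        d = OUT / "motor" / preset
        d.mkdir(parents=True, exist_ok=True)
        model = presets.motor_preset(preset, stimulus_time=60.0,
                                     duration=120.0)
        for i in range(20):
            sim = synthetic.simulate_motor_trace(model, duration=120.0,
                                                 fps=250.0, seed=rng)
            path = cio.write_motor_trace(sim.trace, d / f"motor_{i:03d}.csv")
            cio.write_motor_sidecar(sim, path)
        print(f"{preset}: 20 motors -> {d}")

    # --- FRET cells: default step protocol, 1% shot noise ---
    d = OUT / "fret"
    d.mkdir(parents=True, exist_ok=True)
    schedule = presets.fret_preset()
    for i in range(20):
        sim = synthetic.simulate_fret_experiment(
            presets.DEFAULT_KINASE_MODEL, presets.DEFAULT_DONOR_BLEACH,
            presets.DEFAULT_ACCEPTOR_BLEACH, presets.DEFAULT_EFRET_CONSTANTS,
            schedule, seed=rng, cell_id=f"cell_{i:03d}")
        cio.write_fret_trace(sim.experiment, d / f"cell_{i:03d}.csv")
        np.savetxt(d / f"cell_{i:03d}_truth.csv",
                   np.column_stack([sim.experiment.t, sim.activity_true,
                                    sim.efret_true]),
                   delimiter=",", header="time_s,activity_true,efret_true",
                   comments="")
    cio.write_schedule(schedule, d / "schedule.yaml")
    print(f"fret: 20 cells -> {d}")

    # --- swarm ring observations: 5 paired replicates per condition ---
    d = OUT / "rings"
    d.mkdir(parents=True, exist_ok=True)
    calib = presets.DEFAULT_RING_CALIBRATION
    rows = []
    for cond in ("wt_kanamycin", "aer_null"):
        for rep in range(5):
            z = presets.ring_preset(cond, 200, rng)
            rows.extend(synthetic.simulate_ring_observations(
                calib, z, seed=rng, condition=cond, replicate=f"rep{rep}"))
    cio.write_ring_observations(rows, d / "rings.csv")
    cio.write_calibration(calib, d / "calib.yaml")
    print(f"rings: {len(rows)} observations -> {d}")


if __name__ == "__main__":
    main()
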