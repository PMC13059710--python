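#!/usr/bin/env python
"""Compare vertical cell distributions across swarm conditions.

Reads the ring-diameter observation table from 01_simulate_cohorts.py,
inverts the diameter-to-z calibration, summarizes the z distribution of
each condition (surface-avoiding vs uniformly distributed cells), and
runs the paired t-test between per-replicate mean heights.  Also spot-
checks the image path: renders a handful of rings and localizes them.
Writes results/swarm_ztrack.json.
"""

import json
from pathlib import Path

import numpy as np

from chemosignal import io as cio
from chemosignal import presets, ztrack
from chemosignal.synthetic import render_ring_image

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    d = ROOT.parent / "scratch" / "sim" / "rings"
    if not d.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    df = cio.read_ring_observations(d / "rings.csv")
    calib = cio.read_calibration(d / "calib.yaml")
    summary = ztrack.summarize_colony(df, control="aer_null",
                                      calibration=calib)

    # image-path spot check: render and localize 20 rings
    rng = np.random.default_rng(99)
    errs = []
    for _ in range(20):
        z = rng.uniform(0, 150)
        img = render_ring_image(z, presets.DEFAULT_RING_CALIBRATION, seed=rng)
        est = ztrack.estimate_ring_diameter(img)
        z_hat, _ = ztrack.diameter_to_z(est.diameter_px,
                                        presets.DEFAULT_RING_CALIBRATION)
        errs.append(float(z_hat) - z)
    summary["image_spot_check"] = {
        "n_images": {"value": len(errs), "units": "images"},
        "z_rmse": {"value": float(np.sqrt(np.mean(np.square(errs)))),
                   "units": "um"},
    }

    (ROOT / "swarm_ztrack.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    for cond, s in summary["conditions"].items():
        print(f"{cond}: mean z {s['mean_z']['value']:.1f} um, "
              f"bottom-20um fraction {s['bottom_fraction']['value']:.3f}")
    t = summary["tests"]["wt_kanamycin"]
    print(f"paired t vs aer_null: t = {t['statistic']['value']:.2f}, "
          f"p = {t['pvalue']['value']:.2g}")
    print(f"image spot check z RMSE: "
          f"{summary['image_spot_check']['z_rmse']['value']:.3f} um")
    print(f"wrote {ROOT / 'swarm_ztrack.json'}")


if __name__ == "__main__":
    main()
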