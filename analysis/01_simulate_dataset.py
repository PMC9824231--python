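#!/usr/bin/env python
"""Simulate a small dual-rate recording session and write it to disk.

For a pair of movements (one lower-limb, one upper-limb) this script
generates the 180 Hz gold-standard skeleton stream and a 30 Hz noisy
sensor stream per device, with random start offsets and the configured
camera orientation, and writes them as long-format CSVs with JSON
sidecars under results/synthetic_dataset/.
"""

import sys
from pathlib import Path

import numpy as np

from kinemetry.io import parse_movement_code, write_skeleton_csv
from kinemetry.pipeline import DEFAULT_SENSORS
from kinemetry.synthetic import MotionScript, SimulationConfig, simulate_recording

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_dataset"
MOVEMENTS = ["K-FLEX-FR-1", "S-ABD-IN-1"]
SEED = 20230101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    for code in MOVEMENTS:
        script = MotionScript(code)
        orientation = parse_movement_code(code).camera_orientation
        for spec in DEFAULT_SENSORS:
            config = SimulationConfig(
                camera_orientation=orientation,
                position_noise_sd=spec.position_noise_sd,
                start_offset=float(rng.uniform(0.0, 1.0)),
                seed=SEED,
            )
            rec = simulate_recording(script, config, rng=rng)
            if spec is DEFAULT_SENSORS[0]:
                write_skeleton_csv(rec.gold_stream, OUT / f"{code}_gold.csv")
            stream = rec.sensor.noisy_stream
            stream.source = spec.name
            write_skeleton_csv(stream, OUT / f"{code}_{spec.name}.csv")
            print(
                f"{code} {spec.name:10s} {stream.n_frames:4d} frames at "
                f"{stream.rate:.0f} Hz, offset {config.start_offset:.3f} s"
            )
    print(f"dataset written to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
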