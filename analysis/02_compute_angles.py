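#!/usr/bin/env python
"""Compute in-plane joint angles for every simulated skeleton stream.

Reads the skeleton CSVs written by 01_simulate_dataset.py, builds the
per-frame body basis, measures the movement's joint vector against the
anatomical plane of its movement code, and writes one angle-series CSV
per stream under results/angle_series/.
"""

import sys
from pathlib import Path

from kinemetry.io import read_skeleton_csv, write_angle_csv
from kinemetry.kinematics import angle_series
from kinemetry.synthetic import angle_request_for, movement_definition

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "synthetic_dataset"
OUT = ROOT / "angle_series"


def main() -> int:
    if not IN.exists():
        print("run 01_simulate_dataset.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(IN.glob("*.csv")):
        stream = read_skeleton_csv(path)
        code = stream.movement_code
        series = angle_series(
            stream, angle_request_for(code), movement_definition(code).limb_group
        )
        write_angle_csv(series, OUT / path.name)
        print(
            f"{path.stem:28s} {len(series):4d} samples, "
            f"{series.n_gaps} gaps, range "
            f"{series.values[series.mask].min():6.2f}..{series.values[series.mask].max():6.2f} deg"
        )
    print(f"angle series written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
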