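#!/usr/bin/env python
"""Filter, segment and synchronize the dual-rate angle series.

Reads the angle-series CSVs written by 02_compute_angles.py, applies
the zero-phase Butterworth + moving-average smoothing, trims each
series to its motion execution, aligns every sensor onto the gold
segmentation, and writes one wide aligned-bundle CSV per movement under
results/aligned/ together with the per-sensor residual summary.
"""

import sys
from collections import defaultdict
from pathlib import Path

import numpy as np

from kinemetry.io import read_angle_csv, write_aligned_bundle
from kinemetry.signal_pipeline import smooth, synchronize
from kinemetry.stats import absolute_error, rms_error

ROOT = Path(__file__).resolve().parents[1] / "results"
IN = ROOT / "angle_series"
OUT = ROOT / "aligned"
MOTION_FREQUENCY_HZ = 0.25


def main() -> int:
    if not IN.exists():
        print("run 02_compute_angles.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    by_movement: dict[str, dict[str, Path]] = defaultdict(dict)
    for path in sorted(IN.glob("*.csv")):
        code, sensor = path.stem.rsplit("_", 1)
        by_movement[code][sensor] = path

    for code, streams in by_movement.items():
        gold = smooth(read_angle_csv(streams.pop("gold")))
        gold.source = "gold"
        sensors = []
        for name, path in streams.items():
            s = smooth(read_angle_csv(path))
            s.source = name
            sensors.append(s)
        gold_t, aligned = synchronize(sensors, gold, frequency_hint=MOTION_FREQUENCY_HZ)
        write_aligned_bundle(gold_t, {s.source: s for s in aligned}, OUT / f"{code}.csv")
        for s in aligned:
            err = absolute_error(s, gold_t)
            print(
                f"{code} {s.source:10s} median AE {np.median(err.values):5.2f} deg, "
                f"RMSAE {rms_error(err):5.2f} deg"
            )
    print(f"aligned bundles written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
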