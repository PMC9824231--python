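"""Movement codes, recording-loss accounting, and on-disk formats.

A recording is identified by a movement code,
``joint-movement-orientation-index``: ``K-FLEX-FR-1`` is knee flexion
performed frontally to the sensors, recording 1.  The results sections
of the source study mix English and Portuguese-initial token dialects
(``Q-`` for hip, ``J-`` for knee, ``C-`` for elbow, ``O-`` for
shoulder, ``INL`` for inclined, the ``ADB``/``FLE`` typos); the parser
maps every dialect onto the canonical English tokens.

The availability grid records which recording × volunteer cells could
be analyzed (``o``) or were lost (``x``); a loss in any one sensor
marks the whole recording lost so that every comparison is paired
across all sensors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MovementCodeError
from .series import AngleSeries, SkeletonStream

JOINT_TOKENS = {"K": "K", "J": "K", "H": "H", "Q": "H", "E": "E", "C": "E", "S": "S", "O": "S"}
MOVEMENT_TOKENS = {"FLEX": "FLEX", "FLE": "FLEX", "ABD": "ABD", "ADB": "ABD"}
ORIENTATION_TOKENS = {"FR": "FR", "IN": "IN", "INL": "IN"}

JOINT_NAMES = {"K": "knee", "H": "hip", "E": "elbow", "S": "shoulder"}
MOVEMENT_NAMES = {"FLEX": "flexion", "ABD": "abduction"}
ORIENTATION_NAMES = {"FR": "frontal", "IN": "inclined"}


@dataclass(frozen=True)
class MovementCode:
    """Canonical parsed movement code."""

    joint: str  # K | H | E | S
    movement: str  # FLEX | ABD
    orientation: str  # FR | IN
    index: int | None = None

    def __str__(self) -> str:
        base = f"{self.joint}-{self.movement}-{self.orientation}"
        return base if self.index is None else f"{base}-{self.index}"

    @property
    def limb_group(self) -> str:
        return "lower" if self.joint in ("K", "H") else "upper"

    @property
    def camera_orientation(self) -> float:
        """Subject rotation implied by the orientation token, degrees."""
        return 0.0 if self.orientation == "FR" else 30.0

    def describe(self) -> str:
        parts = [
            JOINT_NAMES[self.joint],
            MOVEMENT_NAMES[self.movement],
            ORIENTATION_NAMES[self.orientation],
        ]
        if self.index is not None:
            parts.append(f"recording {self.index}")
        return "-".join(parts[:3]) + (f"-{parts[3]}" if self.index is not None else "")


def parse_movement_code(text: str) -> MovementCode:
    """Parse a movement code, accepting the known dialect variants."""
    if not text or not text.strip():
        raise MovementCodeError("empty movement code")
    tokens = text.strip().upper().split("-")
    if len(tokens) not in (3, 4):
        raise MovementCodeError(f"movement code {text!r} must have 3 or 4 fields")
    joint, movement, orientation = tokens[:3]
    if joint not in JOINT_TOKENS:
        raise MovementCodeError(f"unknown joint token {joint!r} in {text!r}")
    if movement not in MOVEMENT_TOKENS:
        raise MovementCodeError(f"unknown movement token {movement!r} in {text!r}")
    if orientation not in ORIENTATION_TOKENS:
        raise MovementCodeError(f"unknown orientation token {orientation!r} in {text!r}")
    index: int | None = None
    if len(tokens) == 4:
        try:
            index = int(tokens[3])
        except ValueError as exc:
            raise MovementCodeError(f"bad recording index in {text!r}") from exc
    return MovementCode(
        joint=JOINT_TOKENS[joint],
        movement=MOVEMENT_TOKENS[movement],
        orientation=ORIENTATION_TOKENS[orientation],
        index=index,
    )


class AvailabilityGrid:
    """Recording × volunteer grid of analyzed ('o') / lost ('x') flags."""

    def __init__(self, analyzed: pd.DataFrame):
        if analyzed.isna().any().any():
            raise ValueError("availability grid is incomplete")
        self.analyzed = analyzed.astype(bool)

    @classmethod
    def from_text(cls, text: str) -> "AvailabilityGrid":
        """Parse a whitespace table of rows ``code o x o ...``."""
        rows, codes = [], []
        columns: list[str] | None = None
        for line in text.strip().splitlines():
            fields = line.split()
            if not fields:
                continue
            if set(f.lower() for f in fields[1:]) - {"o", "x"}:
                columns = fields  # header row with volunteer labels
                continue
            codes.append(fields[0])
            rows.append([f.lower() == "o" for f in fields[1:]])
        if not rows:
            raise ValueError("no grid rows found")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("availability grid is incomplete")
        if columns is None or len(columns) - 1 != width:
            columns = ["code"] + [f"volunteer_{i + 1}" for i in range(width)]
        return cls(pd.DataFrame(rows, index=codes, columns=columns[1:]))

    @property
    def total(self) -> int:
        return int(self.analyzed.size)

    def mark_lost(self, code: str, volunteer) -> None:
        self.analyzed.loc[code, volunteer] = False

    def to_text(self) -> str:
        lines = []
        for code, row in self.analyzed.iterrows():
            lines.append(code + " " + " ".join("o" if v else "x" for v in row))
        return "\n".join(lines)


@dataclass(frozen=True)
class LossSummary:
    lost: int
    analyzed: int
    percent_lost: float
    executions: int
    total: int


def loss_accounting(grid: AvailabilityGrid, repetitions_per_recording: int = 5) -> LossSummary:
    """Count lost and analyzed recordings and the resulting executions.

    ``executions`` is analyzed × repetitions: every analyzed recording
    contributes its scripted number of repetitions.
    """
    total = grid.total
    lost = int((~grid.analyzed.to_numpy()).sum())
    analyzed = total - lost
    return LossSummary(
        lost=lost,
        analyzed=analyzed,
        percent_lost=round(100.0 * lost / total, 2),
        executions=analyzed * repetitions_per_recording,
        total=total,
    )


# ---------------------------------------------------------------------------
# File formats


def write_skeleton_csv(stream: SkeletonStream, path: str | Path) -> None:
    """Long-format skeleton CSV plus a JSON sidecar with the metadata."""
    path = Path(path)
    stream.to_frame().to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "movement_code": stream.movement_code,
        "rate_hz": stream.rate,
        "source": stream.source,
        "t0_s": stream.t0,
        **{k: v for k, v in stream.meta.items() if isinstance(v, (int, float, str))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_skeleton_csv(path: str | Path, rate: float | None = None) -> SkeletonStream:
    """Read a long-format skeleton CSV (frame, time_s, joint, x_m, y_m, z_m)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame", "joint", "x_m", "y_m", "z_m"}
    if not required <= set(df.columns):
        raise ValueError(f"skeleton CSV missing columns {sorted(required - set(df.columns))}")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if rate is None:
        rate = meta.get("rate_hz")
    if rate is None:
        times = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        if times.size < 2:
            raise ValueError("cannot infer the sampling rate from one frame")
        rate = 1.0 / float(np.median(np.diff(times)))
    joints = {}
    for joint, g in df.groupby("joint"):
        g = g.sort_values("frame")
        joints[joint] = g[["x_m", "y_m", "z_m"]].to_numpy()
    return SkeletonStream(
        joints=joints,
        rate=float(rate),
        movement_code=meta.get("movement_code"),
        source=meta.get("source"),
        t0=float(meta.get("t0_s", 0.0)),
    )


def read_skeleton_wide_csv(path: str | Path, rate: float) -> SkeletonStream:
    """Read a wide skeleton CSV with ``<joint>_{x,y,z}`` columns per frame."""
    df = pd.read_csv(path)
    joints: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            joints[name] = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()
    if not joints:
        raise ValueError("no <joint>_x/_y/_z column triples found")
    return SkeletonStream(joints=joints, rate=rate)


def write_angle_csv(series: AngleSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_angle_csv(path: str | Path, rate: float | None = None) -> AngleSeries:
    df = pd.read_csv(path)
    if rate is None:
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t)))
    return AngleSeries(
        values=df["angle_deg"].to_numpy(),
        rate=float(rate),
        mask=df["valid"].to_numpy().astype(bool) if "valid" in df.columns else None,
        t0=float(df["time_s"].iloc[0]),
    )


def write_aligned_bundle(
    gold: AngleSeries, sensors: dict[str, AngleSeries], path: str | Path
) -> None:
    """Wide CSV (time, gold, one column per sensor) of synchronized series."""
    data = {"time_s": gold.times, "gold": gold.values}
    for name, s in sensors.items():
        if len(s) != len(gold):
            raise ValueError(f"sensor {name!r} is not aligned to the gold length")
        data[name] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_aligned_bundle(path: str | Path, rate: float) -> tuple[AngleSeries, dict[str, AngleSeries]]:
    df = pd.read_csv(path)
    gold = AngleSeries(df["gold"].to_numpy(), rate=rate, source="gold",
                       t0=float(df["time_s"].iloc[0]))
    sensors = {
        c: AngleSeries(df[c].to_numpy(), rate=rate, source=c, t0=gold.t0)
        for c in df.columns
        if c not in ("time_s", "gold")
    }
    return gold, sensors
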