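"""Core in-memory containers: angle series and skeleton streams.

A :class:`SkeletonStream` is the per-frame named-3D-joint structure
produced by a tracking sensor (or by the synthetic generator); an
:class:`AngleSeries` is the 1-D angle-versus-frame signal derived from it.
Both carry their sampling rate and provenance so the dual-rate signal
pipeline can reason about time without side channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd


@dataclass
class AngleSeries:
    """Angle-versus-frame signal in degrees.

    Parameters
    ----------
    values:
        Angle per frame, degrees. May contain NaN at gap positions.
    rate:
        Sampling rate in Hz.
    movement_code:
        Canonical movement code (e.g. ``"K-FLEX-FR-1"``) if known.
    source:
        Which stream produced the series (sensor name or ``"gold"``).
    mask:
        Boolean validity flags, ``True`` where the sample is usable.
        Defaults to finite values.
    t0:
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    movement_code: str | None = None
    source: str | None = None
    mask: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AngleSeries values must be 1-D")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def n_gaps(self) -> int:
        return int((~self.mask).sum())

    def with_values(self, values: np.ndarray, *, mask: np.ndarray | None = None) -> "AngleSeries":
        """Copy of the series with new samples (provenance preserved)."""
        new = replace(self, values=np.asarray(values, dtype=float))
        new.mask = np.isfinite(new.values) if mask is None else np.asarray(mask, bool)
        return new

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "time_s": self.times,
                "angle_deg": self.values,
                "valid": self.mask.astype(int),
            }
        )


class SkeletonFrame:
    """One frame of a skeleton stream: a joint-name → 3-vector mapping."""

    def __init__(self, joints: Mapping[str, np.ndarray], index: int = 0, time: float = 0.0):
        self.joints = {k: np.asarray(v, dtype=float) for k, v in joints.items()}
        self.index = index
        self.time = time

    def __getitem__(self, joint: str) -> np.ndarray:
        return self.joints[joint]

    def __contains__(self, joint: str) -> bool:
        return joint in self.joints

    def keys(self):
        return self.joints.keys()


@dataclass
class SkeletonStream:
    """Per-frame named 3D joint positions with a sampling rate.

    ``joints`` maps joint name → array of shape ``(n_frames, 3)`` in
    sensor coordinates (x right, y down, z away from the camera, metres).
    """

    joints: dict[str, np.ndarray]
    rate: float
    movement_code: str | None = None
    source: str | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = None
        for name, arr in self.joints.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"joint {name!r} must have shape (n_frames, 3)")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all joints must share the frame count")
            self.joints[name] = arr
        if n is None:
            raise ValueError("stream must contain at least one joint")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.joints.values())).shape[0]

    @property
    def joint_names(self) -> list[str]:
        return list(self.joints)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def frame(self, j: int) -> SkeletonFrame:
        return SkeletonFrame(
            {name: arr[j] for name, arr in self.joints.items()},
            index=j,
            time=self.t0 + j / self.rate,
        )

    def frames(self) -> Iterator[SkeletonFrame]:
        for j in range(self.n_frames):
            yield self.frame(j)

    def positions(self) -> np.ndarray:
        """All joint positions stacked as ``(n_frames, n_joints, 3)``."""
        return np.stack([self.joints[name] for name in self.joints], axis=1)

    def map_positions(self, fn) -> "SkeletonStream":
        """Apply ``fn`` (array of (n,3) → (n,3)) to every joint track."""
        return SkeletonStream(
            joints={name: fn(arr) for name, arr in self.joints.items()},
            rate=self.rate,
            movement_code=self.movement_code,
            source=self.source,
            t0=self.t0,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (frame, time_s, joint, x_m, y_m, z_m)."""
        records = []
        times = self.times
        for name, arr in self.joints.items():
            records.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(self.n_frames),
                        "time_s": times,
                        "joint": name,
                        "x_m": arr[:, 0],
                        "y_m": arr[:, 1],
                        "z_m": arr[:, 2],
                    }
                )
            )
        return (
            pd.concat(records, ignore_index=True)
            .sort_values(["frame", "joint"], kind="stable")
            .reset_index(drop=True)
        )
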