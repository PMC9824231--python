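"""Pinhole camera geometry: projection, depth back-projection, overlay.

An RGB tracker reports a joint as a pixel coordinate (xp, yp); the
depth image supplies the metric range z at that pixel.  Under the
pinhole model with focal length f (pixels) and principal point
(xo, yo), similar triangles give the sensor-frame world coordinates

    xw = (xp - xo) * z / f,   yw = (yp - yo) * z / f,   zw = z.

Coordinates follow the image convention: origin top-left, x right,
y down, z away from the camera.  The flip from image "down" to
anatomical "up" is applied once, in the body-basis construction of
:mod:`kinemetry.kinematics`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AsynchronousFrameError, InvalidDepthError


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal length and principal point in pixels."""

    f: float
    xo: float
    yo: float
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("focal length must be positive")
        if not (0 <= self.xo < self.width and 0 <= self.yo < self.height):
            raise ValueError("principal point must lie inside the image")


@dataclass(frozen=True)
class PixelLandmark:
    """A 2D joint estimate in image coordinates (sub-pixel floats kept)."""

    xp: float
    yp: float
    joint: str = ""
    confidence: float | None = None


def backproject(pixels, z, k: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel coordinates plus depth into 3D sensor coordinates.

    Parameters
    ----------
    pixels:
        ``(..., 2)`` array of (xp, yp), or a :class:`PixelLandmark`.
    z:
        Depth in metres, broadcastable to ``pixels[..., 0]``.
    k:
        Camera intrinsics.

    Returns
    -------
    ``(..., 3)`` array of (xw, yw, zw) metres.

    Raises
    ------
    InvalidDepthError
        If any depth is non-positive or non-finite.
    """
    if isinstance(pixels, PixelLandmark):
        pixels = np.array([pixels.xp, pixels.yp])
    p = np.asarray(pixels, dtype=float)
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)) or np.any(z <= 0):
        raise InvalidDepthError("depth must be finite and > 0")
    xw = (p[..., 0] - k.xo) * z / k.f
    yw = (p[..., 1] - k.yo) * z / k.f
    return np.stack([xw, yw, np.broadcast_to(z, xw.shape)], axis=-1)


def project(points, k: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection of sensor-frame 3D points onto the image plane.

    Inverse of :func:`backproject`; requires all z > 0.
    """
    w = np.asarray(points, dtype=float)
    z = w[..., 2]
    if np.any(z <= 0) or not np.all(np.isfinite(z)):
        raise InvalidDepthError("points must lie in front of the camera (z > 0)")
    xp = k.xo + w[..., 0] * k.f / z
    yp = k.yo + w[..., 1] * k.f / z
    return np.stack([xp, yp], axis=-1)


class DepthFrame:
    """A depth image, dense or sparse, sampled at integer pixels.

    Invalid depths are encoded as 0 or NaN.  Lookup at a landmark rounds
    the sub-pixel coordinate to the nearest pixel; if that pixel is
    invalid, the median of the valid depths in its 3x3 neighbourhood is
    used; if none are valid the sample is NaN (flagged, not dropped).
    """

    def __init__(self, values: np.ndarray, time: float = 0.0):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("depth frame must be 2-D (rows, cols)")
        self.time = time

    @classmethod
    def from_points(
        cls,
        u: np.ndarray,
        v: np.ndarray,
        z: np.ndarray,
        shape: tuple[int, int],
        time: float = 0.0,
    ) -> "DepthFrame":
        """Sparse constructor from per-landmark (u, v, z_m) rows.

        ``u`` is the column (x) and ``v`` the row (y) pixel coordinate;
        unlisted pixels are invalid (0).
        """
        frame = np.zeros(shape, dtype=float)
        rows = np.rint(np.asarray(v, float)).astype(int)
        cols = np.rint(np.asarray(u, float)).astype(int)
        inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        frame[rows[inside], cols[inside]] = np.asarray(z, float)[inside]
        return cls(frame, time=time)

    def sample(self, xp: float, yp: float) -> float:
        """Depth at a (possibly sub-pixel) landmark position; NaN if unusable."""
        h, w = self.values.shape
        col = int(round(float(xp)))
        row = int(round(float(yp)))
        if not (0 <= row < h and 0 <= col < w):
            return float("nan")
        z = self.values[row, col]
        if np.isfinite(z) and z > 0:
            return float(z)
        patch = self.values[max(row - 1, 0) : row + 2, max(col - 1, 0) : col + 2]
        valid = patch[np.isfinite(patch) & (patch > 0)]
        if valid.size:
            return float(np.median(valid))
        return float("nan")


def overlay_depth(
    landmarks: Sequence[PixelLandmark],
    depth: DepthFrame,
    k: CameraIntrinsics,
    *,
    landmark_time: float | None = None,
    rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superimpose 2D landmarks onto a depth frame and back-project.

    Returns ``(points, valid)`` where ``points`` has one (xw, yw, zw) row
    per input landmark (NaN rows where the depth was unusable) and
    ``valid`` flags usable rows.  Output length always equals input
    length: invalid depths are flagged, never silently dropped.

    Raises
    ------
    AsynchronousFrameError
        If ``landmark_time`` is given and differs from the depth frame
        timestamp by more than half a frame period (``rate`` required).
    """
    if landmark_time is not None:
        if rate is None:
            raise ValueError("rate is required to check frame synchrony")
        if abs(landmark_time - depth.time) > 0.5 / rate:
            raise AsynchronousFrameError(
                f"depth frame at t={depth.time:.4f}s is not within half a frame "
                f"period of landmarks at t={landmark_time:.4f}s"
            )
    points = np.full((len(landmarks), 3), np.nan)
    valid = np.zeros(len(landmarks), dtype=bool)
    for i, lm in enumerate(landmarks):
        z = depth.sample(lm.xp, lm.yp)
        if np.isfinite(z) and z > 0:
            points[i] = backproject(np.array([lm.xp, lm.yp]), z, k)
            valid[i] = True
    return points, valid
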