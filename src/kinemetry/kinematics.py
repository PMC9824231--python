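"""ISB-style body coordinate systems and in-plane joint angles.

Joint angles are defined in a body-anchored orthonormal basis (a joint
coordinate system in the ISB sense) rather than in sensor coordinates,
so that the measured angle is invariant to where the camera stands.
The basis is built per frame from trunk/pelvis landmarks:

* ŷ runs up the trunk (mid-spine → spine-top for the upper limbs,
  spine-base → mid-spine for the lower limbs);
* x̂ is the left-hip → right-hip direction orthogonalized against ŷ
  (medio-lateral axis);
* ẑ = x̂ × ŷ completes a right-handed frame (anterior–posterior axis).

A sensor-frame vector v is expressed in body coordinates through the
change of basis v_bc = B⁻¹ v_sc where B has the basis vectors as
columns; B is orthonormal so B⁻¹ = Bᵀ.

An anatomical plane is defined in body coordinates by its normal and a
reference axis lying in the plane.  The monoplanar joint angle is the
angle between the moving (distal − proximal) vector and the reference
axis, provided the moving vector lies in the plane: its angle to the
plane normal must be within a configurable tolerance of 90°, otherwise
an out-of-plane error is raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateBasisError,
    DegenerateVectorError,
    EmptySeriesError,
    MissingJointError,
    OutOfPlaneError,
)
from .series import AngleSeries, SkeletonFrame, SkeletonStream

_EPS = 1e-12


def _unit(v: np.ndarray, err: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateBasisError(err)
    return v / n


@dataclass(frozen=True)
class BodyBasis:
    """Orthonormal right-handed body axes expressed in sensor coordinates."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            v = np.asarray(v, dtype=float)
            object.__setattr__(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise DegenerateBasisError(f"basis vector {name} is not unit")
        if (
            abs(self.x @ self.y) > 1e-9
            or abs(self.x @ self.z) > 1e-9
            or abs(self.y @ self.z) > 1e-9
        ):
            raise DegenerateBasisError("basis vectors are not orthogonal")
        if np.linalg.norm(np.cross(self.x, self.y) - self.z) > 1e-9:
            raise DegenerateBasisError("basis is not right-handed")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def matrix(self) -> np.ndarray:
        """Basis vectors as columns (the change-of-basis matrix B)."""
        return np.column_stack([self.x, self.y, self.z])


# Anatomical planes in body coordinates.  The reference axis is the
# in-plane direction against which the joint angle is measured: the
# trunk-down direction -ŷ for frontal and sagittal movements (so the
# anatomical neutral, limb hanging along the trunk, reads 0° and full
# elevation 180°), the medio-lateral axis x̂ for horizontal ones.
@dataclass(frozen=True)
class AnatomicalPlane:
    name: str
    normal: np.ndarray
    reference_axis: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        r = np.asarray(self.reference_axis, dtype=float)
        if abs(np.linalg.norm(n) - 1) > 1e-9 or abs(np.linalg.norm(r) - 1) > 1e-9:
            raise ValueError("plane normal and reference axis must be unit vectors")
        if abs(n @ r) > 1e-9:
            raise ValueError("reference axis must lie in the plane")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "reference_axis", r)


PLANES: dict[str, AnatomicalPlane] = {
    "frontal": AnatomicalPlane(
        "frontal", normal=np.array([0.0, 0.0, 1.0]), reference_axis=np.array([0.0, -1.0, 0.0])
    ),
    "sagittal": AnatomicalPlane(
        "sagittal", normal=np.array([1.0, 0.0, 0.0]), reference_axis=np.array([0.0, -1.0, 0.0])
    ),
    "horizontal": AnatomicalPlane(
        "horizontal", normal=np.array([0.0, 1.0, 0.0]), reference_axis=np.array([1.0, 0.0, 0.0])
    ),
}


@dataclass(frozen=True)
class AngleRequest:
    """Which joint vector to measure, in which plane, at what tolerance.

    ``tolerance_deg`` is the maximum admissible out-of-plane deviation in
    degrees.  The default 90° disables the check; a strict value would
    unpredictably reject noisy tracking data, so rejection is opt-in.
    """

    proximal: str
    distal: str
    plane: AnatomicalPlane
    tolerance_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.tolerance_deg < 0:
            raise ValueError("tolerance must be non-negative")


# Trunk landmarks used for each limb group's basis.  The pelvis-level
# construction for the lower limbs mirrors the trunk one.
_BASIS_JOINTS = {
    "upper": ("spine_mid", "spine_top"),
    "lower": ("spine_base", "spine_mid"),
}


def build_body_basis(frame: SkeletonFrame, limb_group: str = "upper") -> BodyBasis:
    """Build the body coordinate system from one skeleton frame.

    Raises :class:`MissingJointError` if a required trunk/pelvis landmark
    is absent and :class:`DegenerateBasisError` if the landmarks are
    collinear.
    """
    if limb_group not in _BASIS_JOINTS:
        raise ValueError(f"unknown limb group {limb_group!r}")
    lo, hi = _BASIS_JOINTS[limb_group]
    for joint in (lo, hi, "hip_l", "hip_r"):
        if joint not in frame:
            raise MissingJointError(f"basis joint {joint!r} missing from frame {frame.index}")
    # sensor y points down (image convention); the trunk-up ŷ flips it
    y = _unit(frame[hi] - frame[lo], "spine landmarks coincide")
    hip = frame["hip_r"] - frame["hip_l"]
    x_raw = hip - (hip @ y) * y
    x = _unit(x_raw, "hip line collinear with the spine axis")
    z = np.cross(x, y)
    return BodyBasis(x=x, y=y, z=z, origin=frame[lo].copy())


def to_body_coords(v: np.ndarray, basis: BodyBasis) -> np.ndarray:
    """Change of basis from sensor to body coordinates: B⁻¹ v.

    For the orthonormal B of a valid :class:`BodyBasis` this is Bᵀ v and
    preserves the norm; a general inverse is used as a guard if the
    matrix is ever not orthonormal.
    """
    B = basis.matrix
    v = np.asarray(v, dtype=float)
    BtB = B.T @ B
    if np.allclose(BtB, np.eye(3), atol=1e-9):
        return v @ B  # == (B.T @ v.T).T for stacked vectors
    return np.linalg.solve(B, v.T).T


def _angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    cos = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def angle_in_plane(request: AngleRequest, frame: SkeletonFrame, basis: BodyBasis) -> float:
    """Angle of the moving joint vector within an anatomical plane, degrees.

    The moving vector is distal − proximal expressed in body coordinates.
    If its angle to the plane normal deviates from 90° by more than the
    request tolerance, :class:`OutOfPlaneError` is raised; otherwise the
    angle to the in-plane reference axis is returned in [0°, 180°].
    """
    for joint in (request.proximal, request.distal):
        if joint not in frame:
            raise MissingJointError(f"joint {joint!r} missing from frame {frame.index}")
    moving = to_body_coords(frame[request.distal] - frame[request.proximal], basis)
    if np.linalg.norm(moving) < 1e-9:
        raise DegenerateVectorError(
            f"zero-length vector {request.proximal}->{request.distal} at frame {frame.index}"
        )
    deviation = abs(_angle_between_deg(moving, request.plane.normal) - 90.0)
    if deviation > request.tolerance_deg:
        raise OutOfPlaneError(deviation, request.tolerance_deg)
    return _angle_between_deg(moving, request.plane.reference_axis)


def angle_series(
    stream: SkeletonStream,
    request: AngleRequest,
    limb_group: str = "upper",
) -> AngleSeries:
    """Per-frame in-plane angles for a whole stream.

    Frames whose basis cannot be built or whose moving vector is out of
    plane (or degenerate) become gaps — masked NaN samples — which the
    signal pipeline later fills or escalates.  If every frame fails, an
    :class:`EmptySeriesError` is raised.
    """
    if stream.n_frames == 0:
        raise EmptySeriesError("empty skeleton stream")
    values = np.full(stream.n_frames, np.nan)
    for j, frame in enumerate(stream.frames()):
        try:
            basis = build_body_basis(frame, limb_group)
            values[j] = angle_in_plane(request, frame, basis)
        except (MissingJointError, DegenerateBasisError, DegenerateVectorError, OutOfPlaneError):
            continue
    if not np.isfinite(values).any():
        raise EmptySeriesError("no frame yielded a valid angle")
    return AngleSeries(
        values=values,
        rate=stream.rate,
        movement_code=stream.movement_code,
        source=stream.source,
        t0=stream.t0,
    )
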