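"""Body-basis construction, change of basis, and in-plane angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kinemetry import (
    PLANES,
    AngleRequest,
    BodyBasis,
    angle_in_plane,
    angle_series,
    build_body_basis,
    to_body_coords,
)
from kinemetry.errors import (
    DegenerateBasisError,
    DegenerateVectorError,
    MissingJointError,
    OutOfPlaneError,
)
from kinemetry.series import SkeletonFrame, SkeletonStream


def _random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestBuildBodyBasis:
    def test_canonical_pose_gives_identity_up_to_y_flip(self, template):
        # sensor y points down; the body frame flips it (and z) — a 180°
        # rotation about x, which is exactly the image-to-anatomy flip
        basis = build_body_basis(template.frame(), "upper")
        np.testing.assert_allclose(basis.x, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(basis.y, [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(basis.z, [0, 0, -1], atol=1e-12)

    @pytest.mark.parametrize("limb_group", ["upper", "lower"])
    def test_rotated_skeleton_rotates_basis_not_body_coords(self, template, limb_group):
        frame = template.frame()
        R = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        rotated = SkeletonFrame({k: R @ v for k, v in frame.joints.items()})
        b0 = build_body_basis(frame, limb_group)
        b1 = build_body_basis(rotated, limb_group)
        np.testing.assert_allclose(b1.matrix, R @ b0.matrix, atol=1e-9)
        v = frame["wrist_r"] - frame["shoulder_r"]
        np.testing.assert_allclose(
            to_body_coords(R @ v, b1), to_body_coords(v, b0), atol=1e-9
        )

    def test_collinear_landmarks_raise(self):
        # hips on the spine axis: the cross-orthogonalization degenerates
        frame = SkeletonFrame(
            {
                "spine_mid": [0, 0, 2],
                "spine_top": [0, -1, 2],
                "hip_l": [0, 1, 2],
                "hip_r": [0, 2, 2],
            }
        )
        with pytest.raises(DegenerateBasisError):
            build_body_basis(frame, "upper")

    def test_missing_joint_raises(self):
        with pytest.raises(MissingJointError):
            build_body_basis(SkeletonFrame({"spine_mid": [0, 0, 2]}), "upper")

    def test_basis_invariants_enforced(self):
        with pytest.raises(DegenerateBasisError):
            BodyBasis(x=np.array([1.0, 0, 0]), y=np.array([1.0, 0, 0]), z=np.array([0, 0, 1.0]))
        with pytest.raises(DegenerateBasisError):
            # left-handed set
            BodyBasis(x=np.array([1.0, 0, 0]), y=np.array([0, 1.0, 0]), z=np.array([0, 0, -1.0]))


class TestToBodyCoords:
    def test_basis_vector_maps_to_unit_coordinate(self, template):
        basis = build_body_basis(template.frame(), "upper")
        np.testing.assert_allclose(to_body_coords(basis.x, basis), [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(to_body_coords(basis.y, basis), [0, 1, 0], atol=1e-12)

    def test_identity_basis_is_identity(self):
        basis = BodyBasis(
            x=np.array([1.0, 0, 0]), y=np.array([0, 1.0, 0]), z=np.array([0, 0, 1.0])
        )
        v = np.array([0.3, -1.2, 2.5])
        np.testing.assert_allclose(to_body_coords(v, basis), v, atol=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10_000), vx=st.floats(-5, 5), vy=st.floats(-5, 5), vz=st.floats(-5, 5))
    def test_norm_preserved_and_matches_explicit_inverse(self, seed, vx, vy, vz):
        R = _random_rotation(seed)
        basis = BodyBasis(x=R[:, 0], y=R[:, 1], z=R[:, 2])
        v = np.array([vx, vy, vz])
        out = to_body_coords(v, basis)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(v), abs=1e-9)
        np.testing.assert_allclose(out, np.linalg.inv(basis.matrix) @ v, atol=1e-9)


def _frontal_frame(moving_body_vec, basis):
    """A frame whose shoulder→elbow vector equals the given body vector."""
    B = basis.matrix
    joints = {
        "spine_mid": np.array([0.0, 0.05, 2.5]),
        "spine_top": np.array([0.0, -0.20, 2.5]),
        "hip_l": np.array([-0.1, 0.30, 2.5]),
        "hip_r": np.array([0.1, 0.30, 2.5]),
        "shoulder_r": np.array([0.18, -0.15, 2.5]),
    }
    joints["elbow_r"] = joints["shoulder_r"] + B @ np.asarray(moving_body_vec, float)
    return SkeletonFrame(joints)


class TestAngleInPlane:
    @pytest.fixture
    def basis(self, template):
        return build_body_basis(template.frame(), "upper")

    def test_parallel_to_reference_is_zero(self, basis):
        frame = _frontal_frame([0.0, -0.3, 0.0], basis)  # along -ŷ, the reference
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"])
        assert angle_in_plane(req, frame, basis) == pytest.approx(0.0, abs=1e-9)

    def test_in_plane_45_degrees(self, basis):
        s = np.sin(np.radians(45)) * 0.3
        c = np.cos(np.radians(45)) * 0.3
        frame = _frontal_frame([s, -c, 0.0], basis)
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"])
        assert angle_in_plane(req, frame, basis) == pytest.approx(45.0, abs=1e-9)

    def test_out_of_plane_beyond_tolerance_rejected(self, basis):
        tilt = np.radians(10.0)
        v = 0.3 * np.array([0.0, -np.cos(tilt), np.sin(tilt)])  # 10° out of the frontal plane
        frame = _frontal_frame(v, basis)
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"], tolerance_deg=5.0)
        with pytest.raises(OutOfPlaneError):
            angle_in_plane(req, frame, basis)
        # a looser tolerance accepts the same frame
        req_ok = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"], tolerance_deg=15.0)
        assert 0.0 <= angle_in_plane(req_ok, frame, basis) <= 180.0

    def test_zero_length_vector_rejected(self, basis):
        frame = _frontal_frame([0.0, 0.0, 0.0], basis)
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"])
        with pytest.raises(DegenerateVectorError):
            angle_in_plane(req, frame, basis)

    @settings(deadline=None, max_examples=100)
    @given(theta=st.floats(0.1, 179.9), seed=st.integers(0, 1000))
    def test_matches_independent_atan2_computation(self, theta, seed):
        # an independently built 2-D projection: in-plane coordinates are
        # (u, w) = (ref·v, (normal × ref)·v) and the planar angle is atan2
        R = _random_rotation(seed)
        basis = BodyBasis(x=R[:, 0], y=R[:, 1], z=R[:, 2])
        th = np.radians(theta)
        body_vec = 0.3 * np.array([np.sin(th), -np.cos(th), 0.0])
        frame = _frontal_frame(body_vec, basis)
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"])
        got = angle_in_plane(req, frame, basis)
        plane = PLANES["frontal"]
        u = plane.reference_axis @ body_vec
        w = np.cross(plane.normal, plane.reference_axis) @ body_vec
        expected = np.degrees(abs(np.arctan2(w, u)))
        assert got == pytest.approx(expected, abs=1e-6)


class TestAngleSeries:
    def _stream(self, frames):
        joints = {k: np.stack([f.joints[k] for f in frames]) for k in frames[0].keys()}
        return SkeletonStream(joints=joints, rate=30.0)

    def test_constant_pose_gives_constant_series(self, template):
        basis = build_body_basis(template.frame(), "upper")
        frame = _frontal_frame([0.15, -0.26, 0.0], basis)
        stream = self._stream([frame] * 10)
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"])
        out = angle_series(stream, req, "upper")
        assert len(out) == 10
        assert np.ptp(out.values) == pytest.approx(0.0, abs=1e-12)

    def test_out_of_plane_frame_becomes_single_gap(self, template):
        basis = build_body_basis(template.frame(), "upper")
        good = _frontal_frame([0.15, -0.26, 0.0], basis)
        tilt = np.radians(30)
        bad = _frontal_frame(0.3 * np.array([0.0, -np.cos(tilt), np.sin(tilt)]), basis)
        stream = self._stream([good, good, bad, good])
        req = AngleRequest("shoulder_r", "elbow_r", PLANES["frontal"], tolerance_deg=10.0)
        out = angle_series(stream, req, "upper")
        assert out.n_gaps == 1
        assert not out.mask[2]

    def test_rigid_motion_invariance(self, template):
        from kinemetry.synthetic import MotionScript, forward_kinematics, angle_request_for

        script = MotionScript("S-ABD-FR-1", duration=6.0, n_repetitions=1, frequency=0.25)
        from kinemetry.synthetic import generate_angle_trajectory

        traj = generate_angle_trajectory(script, 30.0)
        stream = forward_kinematics(template, traj)
        req = angle_request_for("S-ABD-FR-1")
        base = angle_series(stream, req, "upper")
        R = _random_rotation(99)
        t = np.array([0.4, -0.2, 0.7])
        moved = stream.map_positions(lambda p: p @ R.T + t)
        out = angle_series(moved, req, "upper")
        np.testing.assert_allclose(out.values, base.values, atol=1e-6)

    def test_angles_stay_in_range(self, template):
        from kinemetry.synthetic import MotionScript, forward_kinematics, angle_request_for, generate_angle_trajectory

        script = MotionScript("E-FLEX-IN-1", amplitude=150.0, baseline_angle=5.0)
        traj = generate_angle_trajectory(script, 30.0)
        stream = forward_kinematics(template, traj)
        out = angle_series(stream, angle_request_for("E-FLEX-IN-1"), "upper")
        assert np.all(out.values[out.mask] >= 0.0)
        assert np.all(out.values[out.mask] <= 180.0)
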