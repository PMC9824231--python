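"""Scripted trajectories, forward kinematics and sensor rendering."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from kinemetry import angle_series
from kinemetry.synthetic import (
    MotionScript,
    SimulationConfig,
    angle_request_for,
    default_template,
    forward_kinematics,
    generate_angle_trajectory,
    movement_definition,
    render_sensor_stream,
    simulate_recording,
)


class TestMotionScript:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MotionScript("K-FLEX-FR-1", frequency=1.5)
        with pytest.raises(ValueError):
            MotionScript("K-FLEX-FR-1", amplitude=-1)
        with pytest.raises(ValueError):
            MotionScript("K-FLEX-FR-1", n_repetitions=0)
        with pytest.raises(ValueError):
            MotionScript("K-FLEX-FR-1", duration=3.0)  # < lead_in + n/f

    def test_zero_amplitude_is_constant_baseline(self):
        script = MotionScript("K-FLEX-FR-1", amplitude=0.0, baseline_angle=12.0)
        traj = generate_angle_trajectory(script, 30.0)
        assert np.ptp(traj.values) == 0.0
        assert traj.values[0] == 12.0


class TestGenerateAngleTrajectory:
    def test_peak_count_and_range(self):
        script = MotionScript("K-FLEX-FR-1", amplitude=90.0, frequency=0.5, n_repetitions=5)
        traj = generate_angle_trajectory(script, 180.0)
        peaks, _ = find_peaks(traj.values, prominence=10.0)
        assert len(peaks) == 5
        assert traj.values.max() == pytest.approx(script.baseline_angle + 90.0, abs=1e-9)
        assert traj.values.min() == pytest.approx(script.baseline_angle, abs=1e-9)

    def test_nyquist_peak_count_at_sensor_rate(self):
        # 30 Hz comfortably oversamples a <= 1 Hz movement: all 5 maxima survive
        script = MotionScript("K-FLEX-FR-1", frequency=1.0)
        traj = generate_angle_trajectory(script, 30.0)
        peaks, _ = find_peaks(traj.values, prominence=10.0)
        assert len(peaks) == script.n_repetitions

    def test_shared_timestamps_agree_across_rates(self):
        script = MotionScript("K-FLEX-FR-1")
        lo = generate_angle_trajectory(script, 30.0)
        hi = generate_angle_trajectory(script, 180.0)
        # every 30 Hz sample instant is also a 180 Hz sample instant
        np.testing.assert_array_equal(lo.values, hi.values[::6][: len(lo)])

    def test_rate_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_angle_trajectory(MotionScript("K-FLEX-FR-1", frequency=1.0), 1.5)


class TestForwardKinematics:
    @pytest.fixture
    def script(self):
        return MotionScript("S-ABD-FR-1")

    def test_segment_lengths_preserved(self, template, script):
        traj = generate_angle_trajectory(script, 30.0)
        stream = forward_kinematics(template, traj)
        move = movement_definition(script.movement_code)
        seg = stream.joints[move.distal] - stream.joints[move.proximal]
        lengths = np.linalg.norm(seg, axis=1)
        np.testing.assert_allclose(lengths, template.segment_length(move.distal), atol=1e-9)

    def test_scripted_zero_angle_parallel_to_reference(self, template):
        # at angle 0 the moving vector hangs along the trunk-down reference,
        # i.e. straight down: +y in sensor coordinates
        script = MotionScript("S-ABD-FR-1", amplitude=0.0, baseline_angle=0.0)
        traj = generate_angle_trajectory(script, 30.0)
        stream = forward_kinematics(template, traj)
        v = stream.joints["elbow_r"][0] - stream.joints["shoulder_r"][0]
        v = v / np.linalg.norm(v)
        np.testing.assert_allclose(v, [0.0, 1.0, 0.0], atol=1e-9)

    @pytest.mark.parametrize(
        "code", ["K-FLEX-FR-1", "H-ABD-FR-1", "H-FLEX-IN-1", "E-FLEX-FR-1", "S-ABD-IN-1", "S-FLEX-FR-1"]
    )
    def test_angle_recovery_round_trip(self, template, code):
        script = MotionScript(code, duration=8.0, n_repetitions=1)
        traj = generate_angle_trajectory(script, 30.0)
        stream = forward_kinematics(template, traj)
        move = movement_definition(code)
        out = angle_series(stream, angle_request_for(code), move.limb_group)
        np.testing.assert_allclose(out.values, traj.values, atol=1e-6)

    def test_unknown_movement_rejected(self, template):
        from kinemetry.errors import MovementCodeError

        with pytest.raises(MovementCodeError):
            movement_definition("K-ABD-FR-1")  # knee abduction is not in the repertoire


class TestRenderSensorStream:
    @pytest.fixture
    def stream(self, template):
        traj = generate_angle_trajectory(MotionScript("S-ABD-FR-1"), 30.0)
        return forward_kinematics(template, traj)

    def test_identity_configuration_returns_input(self, stream, intrinsics):
        config = SimulationConfig(position_noise_sd=0.0, camera_orientation=0.0)
        rendered = render_sensor_stream(stream, config, intrinsics)
        for name in stream.joint_names:
            np.testing.assert_array_equal(rendered.noisy_stream.joints[name], stream.joints[name])

    def test_landmark_at_principal_point_is_on_axis(self, intrinsics, template):
        from kinemetry.series import SkeletonStream

        on_axis = SkeletonStream(joints={"wrist_r": np.array([[0.0, 0.0, 2.0]])}, rate=30.0)
        rendered = render_sensor_stream(
            on_axis, SimulationConfig(position_noise_sd=0.0), intrinsics
        )
        np.testing.assert_allclose(
            rendered.landmarks2d["wrist_r"][0], [intrinsics.xo, intrinsics.yo], atol=1e-9
        )

    def test_backprojection_recovers_rendered_joints(self, stream, intrinsics):
        from kinemetry import backproject

        config = SimulationConfig(position_noise_sd=0.0, camera_orientation=30.0)
        rendered = render_sensor_stream(stream, config, intrinsics)
        for name in ("shoulder_r", "elbow_r", "ankle_l"):
            px = rendered.landmarks2d[name]
            z = rendered.depth[name]
            world = backproject(px, z, intrinsics)
            np.testing.assert_allclose(world, rendered_world(rendered, name), atol=1e-6)

    def test_deterministic_under_seed(self, stream, intrinsics):
        config = SimulationConfig(position_noise_sd=0.005, seed=42)
        a = render_sensor_stream(stream, config, intrinsics)
        b = render_sensor_stream(stream, config, intrinsics)
        for name in stream.joint_names:
            np.testing.assert_array_equal(a.noisy_stream.joints[name], b.noisy_stream.joints[name])

    def test_joint_behind_camera_rejected_with_log(self, intrinsics, caplog):
        from kinemetry.series import SkeletonStream

        behind = SkeletonStream(
            joints={"wrist_r": np.array([[0.0, 0.0, 2.0], [0.0, 0.0, -1.0]])}, rate=30.0
        )
        with caplog.at_level("WARNING"):
            rendered = render_sensor_stream(
                behind, SimulationConfig(position_noise_sd=0.0), intrinsics
            )
        assert rendered.rejected_frames == [1]
        assert np.isnan(rendered.landmarks2d["wrist_r"][1]).all()
        assert "behind the camera" in caplog.text


def rendered_world(rendered, name):
    """The rotated (noise-free) 3D track the renderer projected."""
    return rendered.noisy_stream.joints[name]


class TestSimulateRecording:
    def test_determinism_bit_identical(self):
        script = MotionScript("K-FLEX-FR-1")
        config = SimulationConfig(seed=7, start_offset=0.4)
        a = simulate_recording(script, config)
        b = simulate_recording(script, config)
        for name in a.gold_stream.joint_names:
            np.testing.assert_array_equal(a.gold_stream.joints[name], b.gold_stream.joints[name])
            np.testing.assert_array_equal(
                a.sensor.noisy_stream.joints[name], b.sensor.noisy_stream.joints[name]
            )

    def test_dual_rate_clocks(self):
        script = MotionScript("K-FLEX-FR-1")
        rec = simulate_recording(script, SimulationConfig(seed=1, start_offset=0.5))
        assert rec.gold_truth.rate == 180.0
        assert rec.sensor_truth.rate == 30.0
        assert rec.sensor_truth.t0 == pytest.approx(0.5)
        # the sensor's own clock is reset to zero
        assert rec.sensor.noisy_stream.t0 == 0.0
        assert rec.sensor.noisy_stream.meta["start_offset"] == pytest.approx(0.5)
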