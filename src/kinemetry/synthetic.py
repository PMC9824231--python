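"""Synthetic motion generator: scripted angles, forward kinematics, rendering.

The study conditions this module emulates: slow monoplanar limb
movements (well under 1 Hz), five repetitions per recording, a subject
about 2.5 m from the cameras in one of two orientations (0° or 30°
about the vertical axis), a 180 Hz marker-based gold-standard stream
against 30 Hz tracking sensors, additive landmark noise, and random
per-stream start offsets.

The scripted trajectory is a raised cosine per repetition — the signal
starts and ends at the baseline angle, rises to baseline + amplitude
once per repetition — which matches how guided flexion/abduction
executions look and gives exactly one peak per repetition for the
peak-based synchronization downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraIntrinsics, project
from .errors import MovementCodeError
from .kinematics import PLANES, AngleRequest, build_body_basis, to_body_coords
from .series import AngleSeries, SkeletonFrame, SkeletonStream

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotionScript:
    """One recording's scripted movement.

    Defaults are the generator's study conditions: a 90° excursion from a
    10° baseline, one repetition per 4 s (0.25 Hz), five repetitions, and
    a 2 s tail at baseline after the last repetition.
    """

    movement_code: str
    amplitude: float = 90.0
    frequency: float = 0.25
    n_repetitions: int = 5
    baseline_angle: float = 10.0
    lead_in: float = 1.5
    duration: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.frequency <= 1.0):
            raise ValueError("movement frequency must be in (0, 1] Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.baseline_angle < 0 or self.baseline_angle + self.amplitude > 180:
            raise ValueError("scripted angles must stay within [0°, 180°]")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")
        if self.lead_in < 0:
            raise ValueError("lead-in must be non-negative")
        if self.duration is None:
            object.__setattr__(self, "duration", self.lead_in + self.active_time + 2.0)
        if self.duration < self.lead_in + self.active_time:
            raise ValueError("duration shorter than the scripted repetitions")

    @property
    def active_time(self) -> float:
        """Seconds spent moving: n_repetitions / frequency."""
        return self.n_repetitions / self.frequency

    def angle_at(self, t: np.ndarray) -> np.ndarray:
        """Continuous scripted angle (degrees) at time(s) ``t`` seconds.

        The subject holds the baseline for ``lead_in`` seconds (so every
        stream records some pre-movement hold even after its start
        offset), executes the repetitions, then holds baseline again.
        """
        t = np.asarray(t, dtype=float) - self.lead_in
        active = (t >= 0) & (t <= self.active_time)
        phase = 2 * np.pi * self.frequency * t
        wave = self.baseline_angle + self.amplitude * 0.5 * (1 - np.cos(phase))
        return np.where(active, wave, self.baseline_angle)


@dataclass(frozen=True)
class SimulationConfig:
    """Dual-rate acquisition conditions for one synthetic recording."""

    gold_rate: float = 180.0
    sensor_rate: float = 30.0
    position_noise_sd: float = 0.005
    gold_noise_sd: float = 0.0005
    start_offset: float = 0.0
    seed: int = 0
    dropout_probability: float = 0.15
    camera_orientation: float = 0.0
    subject_distance: float = 2.5

    def __post_init__(self) -> None:
        if not self.gold_rate > self.sensor_rate:
            raise ValueError("gold rate must exceed the sensor rate")
        if self.position_noise_sd < 0 or self.gold_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.dropout_probability < 1:
            raise ValueError("dropout probability must be in [0, 1)")

    def check_nyquist(self, frequency: float) -> None:
        if self.sensor_rate < 2 * frequency:
            raise ValueError(
                f"sensor rate {self.sensor_rate} Hz undersamples a "
                f"{frequency} Hz movement"
            )


@dataclass(frozen=True)
class SkeletonTemplate:
    """Canonical upright skeleton: joint positions plus parent links.

    Positions are in sensor coordinates (x right, y down, z depth,
    metres) for a subject standing at ``positions['pelvis']`` facing the
    camera with both arms hanging.
    """

    positions: dict[str, np.ndarray]
    parents: dict[str, str | None]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", {k: np.asarray(v, float) for k, v in self.positions.items()}
        )
        for child, parent in self.parents.items():
            if parent is None:
                continue
            if parent not in self.positions or child not in self.positions:
                raise ValueError(f"link {parent!r}->{child!r} references unknown joint")
            if self.segment_length(child) <= 0:
                raise ValueError(f"segment {parent!r}->{child!r} has zero length")
        # acyclicity: walking up from every joint must terminate at a root
        for joint in self.parents:
            seen = set()
            node: str | None = joint
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in skeleton hierarchy at {node!r}")
                seen.add(node)
                node = self.parents.get(node)

    def segment_length(self, child: str) -> float:
        parent = self.parents[child]
        if parent is None:
            raise ValueError(f"{child!r} is a root joint")
        return float(np.linalg.norm(self.positions[child] - self.positions[parent]))

    def descendants(self, joint: str) -> list[str]:
        """``joint`` plus every joint below it in the hierarchy."""
        out = [joint]
        frontier = [joint]
        while frontier:
            node = frontier.pop()
            kids = [c for c, p in self.parents.items() if p == node]
            out.extend(kids)
            frontier.extend(kids)
        return out

    def frame(self) -> SkeletonFrame:
        return SkeletonFrame(self.positions)


def default_template(distance: float = 2.5) -> SkeletonTemplate:
    """Average-stature adult template standing ``distance`` metres away."""
    z = distance
    positions = {
        "pelvis": (0.00, 0.30, z),
        "hip_l": (-0.10, 0.30, z),
        "hip_r": (0.10, 0.30, z),
        "spine_base": (0.00, 0.30, z),
        "spine_mid": (0.00, 0.05, z),
        "spine_top": (0.00, -0.20, z),
        "shoulder_l": (-0.18, -0.15, z),
        "shoulder_r": (0.18, -0.15, z),
        "elbow_l": (-0.18, 0.13, z),
        "elbow_r": (0.18, 0.13, z),
        "wrist_l": (-0.18, 0.40, z),
        "wrist_r": (0.18, 0.40, z),
        "knee_l": (-0.10, 0.72, z),
        "knee_r": (0.10, 0.72, z),
        "ankle_l": (-0.10, 1.12, z),
        "ankle_r": (0.10, 1.12, z),
    }
    parents = {
        "pelvis": None,
        "hip_l": "pelvis",
        "hip_r": "pelvis",
        "spine_base": None,
        "spine_mid": "spine_base",
        "spine_top": "spine_mid",
        "shoulder_l": "spine_top",
        "shoulder_r": "spine_top",
        "elbow_l": "shoulder_l",
        "elbow_r": "shoulder_r",
        "wrist_l": "elbow_l",
        "wrist_r": "elbow_r",
        "knee_l": "hip_l",
        "knee_r": "hip_r",
        "ankle_l": "knee_l",
        "ankle_r": "knee_r",
    }
    positions = {k: np.array(v, dtype=float) for k, v in positions.items()}
    return SkeletonTemplate(positions=positions, parents=parents)


@dataclass(frozen=True)
class MovementDefinition:
    """Joint pair, anatomical plane and limb group driven by a movement."""

    proximal: str
    distal: str
    plane: str
    limb_group: str


# Monoplanar movement repertoire: right-side joints, measured against the
# trunk-down reference axis of the relevant plane.
MOVEMENT_DEFS: dict[tuple[str, str], MovementDefinition] = {
    ("K", "FLEX"): MovementDefinition("knee_r", "ankle_r", "sagittal", "lower"),
    ("H", "ABD"): MovementDefinition("hip_r", "knee_r", "frontal", "lower"),
    ("H", "FLEX"): MovementDefinition("hip_r", "knee_r", "sagittal", "lower"),
    ("E", "FLEX"): MovementDefinition("elbow_r", "wrist_r", "sagittal", "upper"),
    ("S", "ABD"): MovementDefinition("shoulder_r", "elbow_r", "frontal", "upper"),
    ("S", "FLEX"): MovementDefinition("shoulder_r", "elbow_r", "sagittal", "upper"),
}


def movement_definition(movement_code: str) -> MovementDefinition:
    from .io import parse_movement_code  # local import: io also imports series

    code = parse_movement_code(movement_code)
    key = (code.joint, code.movement)
    if key not in MOVEMENT_DEFS:
        raise MovementCodeError(f"no movement definition for {movement_code!r}")
    return MOVEMENT_DEFS[key]


def angle_request_for(movement_code: str, tolerance_deg: float = 90.0) -> AngleRequest:
    """The angle request a movement code implies (joint pair + plane)."""
    d = movement_definition(movement_code)
    return AngleRequest(d.proximal, d.distal, PLANES[d.plane], tolerance_deg)


def generate_angle_trajectory(script: MotionScript, rate: float, t0: float = 0.0) -> AngleSeries:
    """Sample the scripted trajectory at ``rate`` Hz starting at ``t0`` s.

    The sampled signal has exactly ``n_repetitions`` maxima and range
    [baseline, baseline + amplitude].  ``rate`` below twice the movement
    frequency violates the sampling theorem and is rejected.
    """
    if rate < 2 * script.frequency:
        raise ValueError(
            f"rate {rate} Hz undersamples a {script.frequency} Hz movement"
        )
    n = int(np.floor((script.duration - t0) * rate)) + 1
    if n < 1:
        raise ValueError("start offset beyond the recording duration")
    t = t0 + np.arange(n) / rate
    return AngleSeries(
        values=script.angle_at(t),
        rate=rate,
        movement_code=script.movement_code,
        source="script",
        t0=t0,
    )


def _rodrigues(v: np.ndarray, axis: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` about unit ``axis`` by angle(s) ``theta`` (rad)."""
    theta = np.asarray(theta, float)[..., None]
    c, s = np.cos(theta), np.sin(theta)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def forward_kinematics(
    template: SkeletonTemplate,
    angles: AngleSeries,
    movement: MovementDefinition | None = None,
) -> SkeletonStream:
    """Pose the template so the scripted angle holds at every frame.

    The moving segment (distal joint and everything below it) is rotated
    rigidly about the anatomical-plane normal, in body coordinates, so
    that the distal − proximal vector lies in the plane and makes the
    scripted angle with the plane's reference axis.  All other joints
    stay at their template positions; segment lengths are preserved
    exactly.
    """
    move = movement or movement_definition(angles.movement_code or "")
    plane = PLANES[move.plane]
    basis = build_body_basis(template.frame(), move.limb_group)
    B = basis.matrix
    prox = template.positions[move.proximal]

    n = len(angles)
    joints: dict[str, np.ndarray] = {
        name: np.tile(pos, (n, 1)) for name, pos in template.positions.items()
    }
    theta = np.radians(angles.values - _rest_angle(template, move, basis))
    for name in template.descendants(move.distal):
        off_bc = to_body_coords(template.positions[name] - prox, basis)
        rotated = _rodrigues(off_bc, plane.normal, theta)  # (n, 3) body coords
        joints[name] = prox + rotated @ B.T
    return SkeletonStream(
        joints=joints,
        rate=angles.rate,
        movement_code=angles.movement_code,
        source="forward_kinematics",
        t0=angles.t0,
    )


def _rest_angle(template: SkeletonTemplate, move: MovementDefinition, basis) -> float:
    """Angle the template's resting segment already makes with the reference."""
    rest = to_body_coords(
        template.positions[move.distal] - template.positions[move.proximal], basis
    )
    plane = PLANES[move.plane]
    cos = rest @ plane.reference_axis / np.linalg.norm(rest)
    return float(np.degrees(np.arccos(np.clip(cos, -1, 1))))


def _vertical_rotation(deg: float) -> np.ndarray:
    """Rotation about the gravity (sensor y) axis by ``deg`` degrees."""
    phi = np.radians(deg)
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class RenderedStream:
    """What a tracking sensor reports for one recording."""

    landmarks2d: dict[str, np.ndarray]  # joint -> (n_frames, 2) pixels
    depth: dict[str, np.ndarray]  # joint -> (n_frames,) true z, metres
    noisy_stream: SkeletonStream  # 3D positions with additive noise
    rejected_frames: list[int] = field(default_factory=list)


def render_sensor_stream(
    stream: SkeletonStream,
    config: SimulationConfig,
    intrinsics: CameraIntrinsics,
    rng: np.random.Generator | None = None,
) -> RenderedStream:
    """Turn a ground-truth stream into what a sensor would report.

    The subject is first rotated by ``config.camera_orientation`` degrees
    about the vertical axis through the pelvis; 2D landmarks are the
    pinhole projection of the rotated joints and the depth channel holds
    their true z.  The noisy 3D stream adds i.i.d. Gaussian position
    noise of ``config.position_noise_sd``; with zero noise it equals the
    rotated input exactly.  Frames with any joint at non-positive depth
    are rejected (NaN landmarks) with a logged reason.  All randomness
    comes from ``rng`` (or a generator seeded by ``config.seed``), so
    identical seeds give bit-identical streams.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.camera_orientation % 360.0 == 0.0:
        rotated = stream.map_positions(lambda p: p.copy())
    else:
        R = _vertical_rotation(config.camera_orientation)
        anchor_name = "pelvis" if "pelvis" in stream.joints else stream.joint_names[0]
        centre = stream.joints[anchor_name][0]
        rotated = stream.map_positions(lambda p: centre + (p - centre) @ R.T)

    pos = rotated.positions()  # (n, j, 3)
    bad = np.any(pos[:, :, 2] <= 0, axis=1)
    rejected = list(np.nonzero(bad)[0])
    for j in rejected:
        log.warning(
            "frame %d rejected: joint behind the camera (z <= 0) for %s",
            j,
            stream.movement_code,
        )

    landmarks2d: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    for name, arr in rotated.joints.items():
        px = np.full((arr.shape[0], 2), np.nan)
        ok = ~bad & (arr[:, 2] > 0)
        if ok.any():
            px[ok] = project(arr[ok], intrinsics)
        landmarks2d[name] = px
        depth[name] = np.where(ok, arr[:, 2], np.nan)

    noisy = rotated.map_positions(
        lambda p: p + rng.normal(0.0, config.position_noise_sd, p.shape)
        if config.position_noise_sd > 0
        else p.copy()
    )
    noisy.source = "sensor"
    # the sensor's own clock starts at zero regardless of the true offset
    noisy.meta["start_offset"] = stream.t0
    noisy.t0 = 0.0
    return RenderedStream(
        landmarks2d=landmarks2d, depth=depth, noisy_stream=noisy, rejected_frames=rejected
    )


@dataclass
class SyntheticRecording:
    """One movement recorded simultaneously by the gold stream and a sensor."""

    script: MotionScript
    config: SimulationConfig
    gold_truth: AngleSeries  # scripted angles on the gold clock
    sensor_truth: AngleSeries  # scripted angles on the (offset) sensor clock
    gold_stream: SkeletonStream
    sensor: RenderedStream
    intrinsics: CameraIntrinsics


def simulate_recording(
    script: MotionScript,
    config: SimulationConfig,
    template: SkeletonTemplate | None = None,
    intrinsics: CameraIntrinsics | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticRecording:
    """Generate the dual-rate recording for one movement script.

    The gold stream samples the motion on [0, duration] at the gold rate
    with its own (sub-millimetre) noise; the sensor stream starts
    ``config.start_offset`` seconds later at the sensor rate, is rotated
    to the configured camera orientation, projected, and perturbed.
    """
    config.check_nyquist(script.frequency)
    if template is None:
        template = default_template(config.subject_distance)
    if intrinsics is None:
        intrinsics = CameraIntrinsics(f=525.0, xo=319.5, yo=239.5, width=640, height=480)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    move = movement_definition(script.movement_code)

    gold_truth = generate_angle_trajectory(script, config.gold_rate)
    gold_stream = forward_kinematics(template, gold_truth, move)
    if config.gold_noise_sd > 0:
        gold_stream = gold_stream.map_positions(
            lambda p: p + rng.normal(0.0, config.gold_noise_sd, p.shape)
        )
    gold_stream.source = "gold"

    sensor_truth = generate_angle_trajectory(
        script, config.sensor_rate, t0=config.start_offset
    )
    sensor_stream = forward_kinematics(template, sensor_truth, move)
    rendered = render_sensor_stream(sensor_stream, config, intrinsics, rng=rng)
    return SyntheticRecording(
        script=script,
        config=config,
        gold_truth=gold_truth,
        sensor_truth=sensor_truth,
        gold_stream=gold_stream,
        sensor=rendered,
        intrinsics=intrinsics,
    )
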