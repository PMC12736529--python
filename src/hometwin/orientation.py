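"""Sensor orientations to anatomical joint angles.

Pipeline: world-frame sensor quaternion streams (arbitrary mounting) are
hemisphere-canonicalized, slerp-resampled onto a common 100 Hz grid, rotated
into segment frames using a two-static-pose TRIAD calibration, and reduced to
per-joint 3-angle Euler decompositions:

* shoulder / trunk: intrinsic Y-X'-Y'' (plane of elevation, elevation, axial
  rotation), elevation reported in [0, 180); the plane is indeterminate at
  zero elevation and is carried forward there;
* elbow / hip / knee / ankle: intrinsic Z-X'-Y'' (flexion first); samples
  within 1 degree of the +-90 degree gimbal configuration are flagged and
  linearly interpolated.

Angles are unwrapped for continuity and low-pass filtered (zero-phase
Butterworth, default 8 Hz) — standard smoothing for 100 Hz human kinematics
that leaves sub-Hz movement content untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation, Slerp

from .taxonomy import CHANNELS, JOINTS, SEGMENTS, angle_names

COMMON_RATE_HZ = 100.0
ANGLE_LOWPASS_HZ = 8.0
PLANE_INDETERMINATE_DEG = 1.0   # elevation below which the plane is undefined
GIMBAL_PROXIMITY_DEG = 1.0      # |second angle| within this of 90 -> flagged
MIN_POSE_SEPARATION_DEG = 15.0

#: gravity direction (unit specific force at rest) in the segment frame for
#: the two static calibration poses: upright N-pose (gravity reaction along
#: the segment long axis +Y) and 90-degree forward-flexed pose
POSE1_GRAVITY_SEG = np.array([0.0, 1.0, 0.0])
POSE2_GRAVITY_SEG = np.array([0.0, 0.0, -1.0])


@dataclass
class QuaternionStream:
    """Unit-quaternion (scalar-first) orientation time series of one sensor."""

    sensor_id: str
    times: np.ndarray          # (n,), s, strictly increasing
    quat_wxyz: np.ndarray      # (n, 4)
    rate_hz: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.quat_wxyz = np.asarray(self.quat_wxyz, float)
        if self.times.size < 1 or self.quat_wxyz.shape != (self.times.size, 4):
            raise ValueError("stream shape mismatch or empty stream")
        norms = np.linalg.norm(self.quat_wxyz, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm within 1e-6")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def canonicalized(self) -> "QuaternionStream":
        """Flip signs so consecutive quaternions stay on one hemisphere."""
        q = self.quat_wxyz.copy()
        dots = np.sum(q[1:] * q[:-1], axis=1)
        flips = np.cumsum(dots < 0) % 2
        q[1:][flips.astype(bool)] *= -1.0
        if q[0, 0] < 0:
            q *= -1.0
        return QuaternionStream(self.sensor_id, self.times, q, self.rate_hz)

    @property
    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quat_wxyz[:, [1, 2, 3, 0]])

    @classmethod
    def from_rotations(
        cls, sensor_id: str, times: np.ndarray, rots: Rotation, rate_hz: float
    ) -> "QuaternionStream":
        q = rots.as_quat()[:, [3, 0, 1, 2]]
        return cls(sensor_id, times, q, rate_hz).canonicalized()


@dataclass
class MountingCalibration:
    """Fixed sensor-to-segment rotation estimated from two static poses."""

    segment: str
    matrix: np.ndarray       # (3, 3), maps sensor-frame vectors to segment frame
    residual_deg: float      # angle between mapped and ideal pose-2 gravity

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if np.max(np.abs(m @ m.T - np.eye(3))) > 1e-9 or np.linalg.det(m) < 0:
            raise ValueError("calibration matrix must be a proper rotation")
        self.matrix = m


def _triad(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    t1 = v1 / np.linalg.norm(v1)
    t2 = np.cross(v1, v2)
    t2 /= np.linalg.norm(t2)
    return np.column_stack([t1, t2, np.cross(t1, t2)])


def calibrate_segment(
    pose1_gravity: np.ndarray,
    pose2_gravity: np.ndarray,
    segment: str = "",
    segment_spec: tuple[np.ndarray, np.ndarray] = (POSE1_GRAVITY_SEG, POSE2_GRAVITY_SEG),
) -> MountingCalibration:
    """TRIAD sensor-to-segment rotation from the two static-pose gravities.

    Pose 1 fixes the segment long axis; pose 2 (non-collinear) fixes the
    remaining heading by Gram-Schmidt; the third axis is their cross product.
    """
    a1 = np.asarray(pose1_gravity, float)
    a2 = np.asarray(pose2_gravity, float)
    a1 = a1 / np.linalg.norm(a1)
    a2 = a2 / np.linalg.norm(a2)
    angle = np.degrees(np.arccos(np.clip(np.dot(a1, a2), -1.0, 1.0)))
    if angle <= MIN_POSE_SEPARATION_DEG or angle >= 180.0 - MIN_POSE_SEPARATION_DEG:
        raise ValueError(
            f"degenerate calibration poses: gravity directions separated by "
            f"{angle:.1f} degrees"
        )
    v1, v2 = segment_spec
    rot = _triad(v1, v2) @ _triad(a1, a2).T
    mapped = rot @ a2
    v2n = v2 / np.linalg.norm(v2)
    residual = np.degrees(np.arccos(np.clip(np.dot(mapped, v2n), -1.0, 1.0)))
    return MountingCalibration(segment=segment, matrix=rot, residual_deg=float(residual))


def resample_slerp(stream: QuaternionStream, target_rate: float,
                   t_start: float | None = None, t_end: float | None = None) -> QuaternionStream:
    """Spherical-linear resampling onto a uniform target grid."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if stream.times.size < 2:
        raise ValueError("need at least 2 samples to resample")
    s = stream.canonicalized()
    t0 = s.times[0] if t_start is None else t_start
    t1 = s.times[-1] if t_end is None else t_end
    if t0 < s.times[0] - 1e-12 or t1 > s.times[-1] + 1e-12:
        raise ValueError("target grid must lie within the stream span")
    k0 = int(np.ceil(round(t0 * target_rate, 9)))
    k1 = int(np.floor(round(t1 * target_rate, 9)))
    grid = np.arange(k0, k1 + 1) / target_rate
    grid = np.clip(grid, s.times[0], s.times[-1])
    rots = Slerp(s.times, s.rotations)(grid)
    return QuaternionStream.from_rotations(s.sensor_id, grid, rots, target_rate)


def synchronize(
    streams: dict[str, QuaternionStream], target_rate: float = COMMON_RATE_HZ
) -> dict[str, QuaternionStream]:
    """Resample all streams onto one grid spanning their common overlap."""
    t0 = max(s.times[0] for s in streams.values())
    t1 = min(s.times[-1] for s in streams.values())
    if t1 <= t0:
        raise ValueError("streams have no temporal overlap")
    return {k: resample_slerp(s, target_rate, t0, t1) for k, s in streams.items()}


def apply_calibration(stream: QuaternionStream, cal: MountingCalibration) -> Rotation:
    """Segment world orientation: sensor rotation composed with the inverse
    mounting rotation."""
    return stream.rotations * Rotation.from_matrix(cal.matrix).inv()


def joint_rotation(parent: Rotation, child: Rotation,
                   parent_times: np.ndarray | None = None,
                   child_times: np.ndarray | None = None) -> Rotation:
    """Relative rotation R_parent^T . R_child per sample."""
    if parent_times is not None and child_times is not None:
        if parent_times.shape != child_times.shape or np.any(
            np.abs(parent_times - child_times) > 1e-9
        ):
            raise ValueError("parent and child streams are on different grids")
    if len(parent) != len(child):
        raise ValueError("parent and child streams are on different grids")
    return parent.inv() * child


def euler_shoulder(rot: Rotation) -> tuple[np.ndarray, np.ndarray]:
    """Y-X'-Y'' decomposition -> (n, 3) [plane, elevation, axial] in degrees.

    Elevation is returned in [0, 180]. Where elevation < 1 degree only the sum
    plane+axial is defined: the plane is carried forward from the last
    well-posed sample (0 at the start) and the axial angle absorbs the rest.
    Returns (angles, indeterminate_mask).
    """
    with warnings.catch_warnings():
        # exact singular samples are expected; they are flagged and handled here
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = rot.as_euler("YXY", degrees=True)
    single = ang.ndim == 1
    ang = np.atleast_2d(ang).copy()
    mask = ang[:, 1] < PLANE_INDETERMINATE_DEG
    if mask.any():
        total = ang[:, 0] + ang[:, 2]
        carried = 0.0
        for i in range(ang.shape[0]):
            if mask[i]:
                ang[i, 0] = carried
                ang[i, 2] = _wrap_deg(total[i] - carried)
            else:
                carried = ang[i, 0]
        # leading indeterminate run: backfill with first good plane if any
        if mask[0] and not mask.all():
            first = int(np.argmin(mask))
            ang[:first, 0] = ang[first, 0]
            ang[:first, 2] = _wrap_deg(total[:first] - ang[first, 0])
    return (ang[0], mask[0]) if single else (ang, mask)


def euler_lower(rot: Rotation, joint: str = "knee") -> tuple[np.ndarray, np.ndarray]:
    """Z-X'-Y'' (flexion-first) decomposition -> (n, 3) degrees.

    Samples with the second angle within 1 degree of +-90 (gimbal proximity)
    are flagged and linearly interpolated from their neighbors.
    Returns (angles, gimbal_mask).
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = rot.as_euler("ZXY", degrees=True)
    single = ang.ndim == 1
    ang = np.atleast_2d(ang).copy()
    mask = np.abs(np.abs(ang[:, 1]) - 90.0) < GIMBAL_PROXIMITY_DEG
    if mask.any() and not mask.all():
        good = ~mask
        idx = np.arange(ang.shape[0])
        for c in range(3):
            col = np.unwrap(ang[:, c], period=360.0)
            col[mask] = np.interp(idx[mask], idx[good], col[good])
            ang[:, c] = col
    return (ang[0], mask[0]) if single else (ang, mask)


def trunk_inclination(thorax_world: Rotation) -> tuple[np.ndarray, np.ndarray]:
    """Thorax orientation relative to the world vertical, Y-X'-Y''."""
    return euler_shoulder(thorax_world)


def _wrap_deg(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


@dataclass
class JointAngleStream:
    """All joint-angle channels on the common grid."""

    times: np.ndarray                  # (n,)
    angles: np.ndarray                 # (n, len(CHANNELS)), deg
    rate_hz: float = COMMON_RATE_HZ
    channels: tuple[str, ...] = CHANNELS
    flags: np.ndarray | None = None    # (n, len(CHANNELS)) bool, True = degraded

    def channel(self, name: str) -> np.ndarray:
        return self.angles[:, self.channels.index(name)]


def _lowpass(angles: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz is None or cutoff_hz <= 0 or angles.shape[0] < 15:
        return angles
    b, a = butter(2, cutoff_hz / (rate_hz / 2.0))
    return filtfilt(b, a, angles, axis=0)


def recover_joint_angles(
    streams: dict[str, QuaternionStream],
    calibrations: dict[str, MountingCalibration],
    rate_hz: float = COMMON_RATE_HZ,
    lowpass_hz: float | None = ANGLE_LOWPASS_HZ,
) -> JointAngleStream:
    """Full orientation pipeline: synchronize, calibrate, decompose, smooth."""
    missing = [s for s in SEGMENTS if s not in streams]
    if missing:
        raise ValueError(f"missing sensor streams for segments: {missing}")
    synced = synchronize(streams, rate_hz)
    times = next(iter(synced.values())).times
    segs = {name: apply_calibration(synced[name], calibrations[name]) for name in SEGMENTS}
    world = Rotation.identity(len(times))

    n = times.size
    angles = np.empty((n, len(CHANNELS)))
    flags = np.zeros((n, len(CHANNELS)), dtype=bool)
    col = 0
    for joint, (parent, child, conv) in JOINTS.items():
        p = world if parent == "world" else segs[parent]
        jr = joint_rotation(p, segs[child])
        if conv == "YXY":
            a, m = euler_shoulder(jr)
        else:
            a, m = euler_lower(jr, joint)
        a = a.copy()
        a[:, 0] = np.unwrap(a[:, 0], period=360.0)
        a[:, 2] = np.unwrap(a[:, 2], period=360.0)
        angles[:, col : col + 3] = a
        flags[:, col : col + 3] = m[:, None]
        col += 3
    angles = _lowpass(angles, rate_hz, lowpass_hz)
    return JointAngleStream(times=times, angles=angles, rate_hz=rate_hz, flags=flags)
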