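"""Simulated sensor observations: body-worn orientation streams and UWB TDOA.

Each of the 12 sensors reports the world orientation of its segment composed
with a fixed, arbitrary mounting rotation, sampled at 225 Hz and perturbed by
small random-axis rotation noise (optionally a slow heading drift). The two
static calibration poses are emulated by the accelerometer gravity readings
they would produce. The UWB tag (carried at the body centroid) yields, at
~5 Hz, range differences to each anchor relative to anchor 1 with Gaussian
ranging noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ..orientation import QuaternionStream
from ..taxonomy import SEGMENTS
from .layout import HomeLayout
from .motion import SubjectTruth

IMU_RATE_HZ = 225.0
UWB_RATE_HZ = 5.0

#: world orientation of every segment in the two static calibration poses:
#: upright N-pose, then 90-degree forward flexion about the world X axis
POSE1_WORLD = Rotation.identity()
POSE2_WORLD = Rotation.from_euler("X", 90, degrees=True)
GRAVITY_WORLD = np.array([0.0, 1.0, 0.0])  # specific force at rest, +up


@dataclass
class CalibrationPoses:
    """Averaged accelerometer gravity readings per sensor in the two poses."""

    pose1: dict[str, np.ndarray]
    pose2: dict[str, np.ndarray]


def _rotation_noise(rng: np.random.Generator, n: int, sd_deg: float) -> Rotation:
    """Random small rotations whose total rotation-angle SD is sd_deg."""
    sd = np.radians(sd_deg) / np.sqrt(3.0)
    return Rotation.from_rotvec(rng.normal(0.0, sd, size=(n, 3)))


def simulate_imu(
    truth: SubjectTruth,
    noise_deg: float = 0.0,
    seed: int = 0,
    rate_hz: float = IMU_RATE_HZ,
    drift_deg_per_min: float = 0.0,
    pose_noise_deg: float = 0.0,
) -> tuple[dict[str, QuaternionStream], CalibrationPoses]:
    """Sensor quaternion streams at 225 Hz plus calibration-pose readings."""
    if noise_deg < 0 or pose_noise_deg < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x10]))
    duration = truth.motion.duration
    n = int(np.floor(round(duration * rate_hz, 9))) + 1
    times = np.arange(n) / rate_hz
    times = times[times <= duration + 1e-12]
    segs = truth.segment_orientations_at(times)

    streams: dict[str, QuaternionStream] = {}
    for name in SEGMENTS:
        sensor_rot = segs[name] * truth.mounting[name]
        if drift_deg_per_min > 0:
            drift = Rotation.from_rotvec(
                np.outer(np.radians(drift_deg_per_min) / 60.0 * times, [0.0, 1.0, 0.0])
            )
            sensor_rot = drift * sensor_rot
        if noise_deg > 0:
            sensor_rot = sensor_rot * _rotation_noise(rng, len(times), noise_deg)
        streams[name] = QuaternionStream.from_rotations(name, times, sensor_rot, rate_hz)

    pose1: dict[str, np.ndarray] = {}
    pose2: dict[str, np.ndarray] = {}
    for name in SEGMENTS:
        for pose_world, store in ((POSE1_WORLD, pose1), (POSE2_WORLD, pose2)):
            sensor_world = pose_world * truth.mounting[name]
            g = sensor_world.inv().apply(GRAVITY_WORLD)
            if pose_noise_deg > 0:
                g = _rotation_noise(rng, 1, pose_noise_deg)[0].apply(g)
            store[name] = g
    return streams, CalibrationPoses(pose1=pose1, pose2=pose2)


@dataclass
class TdoaFrames:
    """UWB range-difference frames relative to the first anchor.

    deltas[k, i-1] = ||p_k - a_i|| - ||p_k - a_1|| for anchors i = 2..N,
    planar distances, anchors in sorted label order.
    """

    times: np.ndarray        # (k,)
    deltas: np.ndarray       # (k, n_anchors - 1), m
    anchor_labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.times)


def true_range_differences(points: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Noiseless planar TDOA range differences for (n, 2) points."""
    d = np.linalg.norm(points[:, None, :] - anchors[None, :, :], axis=2)
    return d[:, 1:] - d[:, :1]


def simulate_uwb(
    truth: SubjectTruth,
    layout: HomeLayout | None = None,
    noise_sd_m: float = 0.0,
    seed: int = 0,
    rate_hz: float = UWB_RATE_HZ,
) -> TdoaFrames:
    """TDOA frames at ~5 Hz from the truth trajectory."""
    layout = layout if layout is not None else truth.layout
    anchors = layout.anchor_array
    if anchors.shape[0] < 4:
        raise ValueError("need at least 4 anchors")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x08]))
    step = max(1, int(round(truth.fs_hz / rate_hz)))
    idx = np.arange(0, truth.times.size, step)
    pts = truth.trajectory[idx]
    deltas = true_range_differences(pts, anchors)
    if noise_sd_m > 0:
        deltas = deltas + rng.normal(0.0, noise_sd_m, size=deltas.shape)
    return TdoaFrames(
        times=truth.times[idx],
        deltas=deltas,
        anchor_labels=tuple(sorted(layout.anchors)),
    )
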