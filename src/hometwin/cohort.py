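"""In-memory cohort builder: ground truth through the full sensing chain.

Convenience layer shared by the analysis drivers, the test suite and the
acceptance script: for each subject it generates schedule + motion, simulates
the 12 orientation sensors, calibrates them from the two static poses, and
recovers the joint-angle stream — returning both truth and reconstruction
without touching disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import orientation as ori
from .config import RunConfig
from .synth import (
    HomeLayout,
    generate_layout,
    generate_schedule,
    simulate_imu,
    synthesize_motion,
)
from .synth.motion import SubjectTruth
from .taxonomy import SEGMENTS


@dataclass
class CohortSubject:
    subject_id: str
    truth: SubjectTruth
    angles: ori.JointAngleStream        # pipeline-recovered joint angles
    calibrations: dict[str, ori.MountingCalibration]

    @property
    def n_common(self) -> int:
        return min(self.angles.angles.shape[0], self.truth.times.size)


def build_subject(
    layout: HomeLayout,
    cfg: RunConfig,
    subject_id: str,
    schedule_seed: int,
    motion_seed: int,
    imu_seed: int,
    mounting_seed: int | None = None,
    noise_deg: float | None = None,
) -> CohortSubject:
    schedule = generate_schedule(layout, cfg.duration_s, schedule_seed, subject_id)
    truth = synthesize_motion(
        schedule, seed=motion_seed, fs_hz=cfg.common_hz, mounting_seed=mounting_seed
    )
    streams, poses = simulate_imu(
        truth,
        noise_deg=cfg.imu_noise_deg if noise_deg is None else noise_deg,
        seed=imu_seed,
        rate_hz=cfg.imu_hz,
        drift_deg_per_min=cfg.imu_drift_deg_per_min,
        pose_noise_deg=cfg.pose_noise_deg,
    )
    cals = {
        seg: ori.calibrate_segment(poses.pose1[seg], poses.pose2[seg], seg)
        for seg in SEGMENTS
    }
    angles = ori.recover_joint_angles(
        streams, cals, rate_hz=cfg.common_hz, lowpass_hz=cfg.angle_lowpass_hz
    )
    return CohortSubject(subject_id, truth, angles, cals)


def build_cohort(cfg: RunConfig) -> tuple[HomeLayout, dict[str, CohortSubject]]:
    """Generate the whole cohort through the sensing + reconstruction chain."""
    layout = generate_layout(cfg.root_seed)
    sched = cfg.subject_seeds("schd")
    motn = cfg.subject_seeds("motn")
    imu = cfg.subject_seeds("imu_")
    out = {}
    for i, sid in enumerate(cfg.subject_ids()):
        out[sid] = build_subject(layout, cfg, sid, sched[i], motn[i], imu[i])
    return layout, out


def classification_streams(
    subjects: dict[str, CohortSubject],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """(recovered angles, truth activity codes, truth rooms) per subject,
    cropped to the common span — the input of the windowing stage."""
    out = {}
    for sid, s in subjects.items():
        n = s.n_common
        out[sid] = (s.angles.angles[:n], s.truth.labels[:n], s.truth.rooms[:n])
    return out


def angle_rmse_by_channel(subject: CohortSubject) -> np.ndarray:
    """Per-channel RMSE (deg) between recovered and truth angles, with
    circular wrapping."""
    n = subject.n_common
    diff = subject.angles.angles[:n] - subject.truth.joint_angles[:n]
    diff = (diff + 180.0) % 360.0 - 180.0
    return np.sqrt((diff**2).mean(axis=0))
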