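"""Skeletal-animation export of the reconstructed motion.

The avatar stand-in is a BVH file: the reduced kinematic chain as the
hierarchy, joint rotations as Z/X/Y rotation channels, and the planar UWB
trajectory as root translation. A compact JSON pose stream (times + per-joint
Euler angles) is written alongside for programmatic consumers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .orientation import JointAngleStream
from .taxonomy import CHANNEL_INDEX, JOINTS, angle_names

#: BVH joint tree: name -> (parent joint or None, offset in meters)
BVH_TREE: dict[str, tuple[str | None, tuple[float, float, float]]] = {
    "pelvis": (None, (0.0, 0.95, 0.0)),
    "trunk": ("pelvis", (0.0, 0.25, 0.0)),
    "shoulder_l": ("trunk", (-0.20, 0.25, 0.0)),
    "elbow_l": ("shoulder_l", (0.0, -0.30, 0.0)),
    "shoulder_r": ("trunk", (0.20, 0.25, 0.0)),
    "elbow_r": ("shoulder_r", (0.0, -0.30, 0.0)),
    "hip_l": ("pelvis", (-0.10, 0.0, 0.0)),
    "knee_l": ("hip_l", (0.0, -0.42, 0.0)),
    "ankle_l": ("knee_l", (0.0, -0.42, 0.0)),
    "hip_r": ("pelvis", (0.10, 0.0, 0.0)),
    "knee_r": ("hip_r", (0.0, -0.42, 0.0)),
    "ankle_r": ("knee_r", (0.0, -0.42, 0.0)),
}

_END_SITES = {"elbow_l", "elbow_r", "ankle_l", "ankle_r", "trunk"}


def _joint_zxy(angles: JointAngleStream, joint: str) -> np.ndarray:
    """Joint rotation as intrinsic Z-X-Y angles (deg) for BVH channels."""
    conv = JOINTS[joint][2]
    cols = [CHANNEL_INDEX[f"{joint}.{n}"] for n in angle_names(joint)]
    a = angles.angles[:, cols]
    if conv == "ZXY":
        return a
    rot = Rotation.from_euler(conv, a, degrees=True)
    return rot.as_euler("ZXY", degrees=True)


def export_pose_stream(
    angles: JointAngleStream,
    trajectory: np.ndarray,
    path: str | Path,
    json_path: str | Path | None = None,
) -> Path:
    """Write a BVH animation (plus JSON pose stream) from joint angles and the
    planar trajectory. The two streams must share one grid."""
    n = angles.angles.shape[0]
    if trajectory.shape[0] != n:
        raise ValueError("angle stream and trajectory are on different grids")
    path = Path(path)

    zxy = {j: _joint_zxy(angles, j) for j in BVH_TREE if j != "pelvis"}
    children: dict[str | None, list[str]] = {}
    for j, (parent, _) in BVH_TREE.items():
        children.setdefault(parent, []).append(j)

    lines: list[str] = ["HIERARCHY"]

    def emit(joint: str, depth: int) -> None:
        indent = "  " * depth
        kind = "ROOT" if depth == 0 else "JOINT"
        off = BVH_TREE[joint][1]
        lines.append(f"{indent}{kind} {joint}")
        lines.append(f"{indent}{{")
        lines.append(f"{indent}  OFFSET {off[0]:.4f} {off[1]:.4f} {off[2]:.4f}")
        if depth == 0:
            lines.append(
                f"{indent}  CHANNELS 6 Xposition Yposition Zposition "
                "Zrotation Xrotation Yrotation"
            )
        else:
            lines.append(f"{indent}  CHANNELS 3 Zrotation Xrotation Yrotation")
        for ch in children.get(joint, []):
            emit(ch, depth + 1)
        if joint in _END_SITES:
            lines.append(f"{indent}  End Site")
            lines.append(f"{indent}  {{")
            lines.append(f"{indent}    OFFSET 0.0000 -0.1500 0.0000")
            lines.append(f"{indent}  }}")
        lines.append(f"{indent}}}")

    emit("pelvis", 0)
    frame_time = 1.0 / angles.rate_hz
    lines.append("MOTION")
    lines.append(f"Frames: {n}")
    lines.append(f"Frame Time: {frame_time:.6f}")

    order = _depth_first_order()
    rows = np.empty((n, 6 + 3 * (len(order) - 1)))
    rows[:, 0] = trajectory[:, 0]
    rows[:, 1] = 0.0
    rows[:, 2] = trajectory[:, 1]
    rows[:, 3:6] = 0.0  # the root (pelvis) does not rotate in this model
    col = 6
    for joint in order[1:]:
        rows[:, col : col + 3] = zxy[joint]
        col += 3
    for r in rows:
        lines.append(" ".join(f"{v:.4f}" for v in r))
    path.write_text("\n".join(lines) + "\n")

    if json_path is not None:
        obj = {
            "rate_hz": angles.rate_hz,
            "joints": order[1:],
            "channel_order": "ZXY",
            "root_translation_xz_m": np.round(trajectory, 4).tolist(),
            "angles_deg": {j: np.round(zxy[j], 3).tolist() for j in order[1:]},
        }
        Path(json_path).write_text(json.dumps(obj))
    return path


def _depth_first_order() -> list[str]:
    children: dict[str | None, list[str]] = {}
    for j, (parent, _) in BVH_TREE.items():
        children.setdefault(parent, []).append(j)
    order: list[str] = []

    def walk(j: str) -> None:
        order.append(j)
        for ch in children.get(j, []):
            walk(ch)

    walk("pelvis")
    return order
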