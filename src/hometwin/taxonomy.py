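"""Activity taxonomy, kinematic chain, and joint-angle channel conventions.

The model body is a reduced kinematic chain driven purely by orientations:
pelvis -> thorax -> upper arms -> forearms, and pelvis -> thighs -> shanks ->
feet (12 segments, matching a 12-sensor wearable montage). Joint angles are
anatomically named 3-angle decompositions of the relative rotation between
adjacent segments:

* shoulder and trunk use an intrinsic Y-X'-Y'' sequence
  (plane of elevation / elevation / axial rotation);
* elbow, hip, knee and ankle use an intrinsic Z-X'-Y'' sequence
  (flexion / ab-adduction or inversion-eversion / axial rotation).

The world frame has +Y vertical (gravity specific force points along +Y for a
resting accelerometer); the floor plane is spanned by X and Z.
"""

from __future__ import annotations

# 19 activities of daily living.
ACTIVITIES: tuple[str, ...] = (
    "tooth_brushing",
    "food_chopping",
    "door_opening",
    "eating_drinking",
    "hair_combing",
    "lying",
    "lying_phone",
    "lie_to_sit",
    "picking_object",
    "pulling_blind",
    "reaching",
    "sitting",
    "sit_to_lie",
    "sit_to_stand",
    "standing",
    "stand_to_sit",
    "walking",
    "walking_phone",
    "working_desk",
)

WALKING_CLASSES = ("walking", "walking_phone")

#: classes that occur as locomotor transitions between stationary episodes
STATIONARY_CLASSES = tuple(a for a in ACTIVITIES if a not in WALKING_CLASSES)

# Rooms an activity may be scheduled in, and the point of interest it happens
# at. Walking classes are path-based and omitted here.
ACTIVITY_ROOMS: dict[str, tuple[tuple[str, str], ...]] = {
    "tooth_brushing": (("bathroom", "mirror"),),
    "food_chopping": (("kitchen", "bench"),),
    "door_opening": (("bathroom", "door"), ("living_room", "balcony_door")),
    "eating_drinking": (("kitchen", "table"),),
    "hair_combing": (("bathroom", "mirror"),),
    "lying": (("bedroom", "bed"),),
    "lying_phone": (("bedroom", "bed"),),
    "lie_to_sit": (("bedroom", "bed"),),
    "picking_object": (
        ("living_room", "sofa"),
        ("bedroom", "bed"),
        ("study", "desk"),
        ("kitchen", "table"),
    ),
    "pulling_blind": (("bedroom", "window"),),
    "reaching": (("kitchen", "fridge"), ("study", "shelf"), ("living_room", "sofa")),
    "sitting": (
        ("living_room", "sofa"),
        ("kitchen", "table"),
        ("bedroom", "bed"),
        ("study", "desk"),
    ),
    "sit_to_lie": (("bedroom", "bed"),),
    "sit_to_stand": (("living_room", "sofa"), ("kitchen", "table"), ("bedroom", "bed")),
    "standing": (
        ("living_room", "sofa"),
        ("kitchen", "bench"),
        ("bathroom", "mirror"),
        ("bedroom", "window"),
        ("study", "shelf"),
    ),
    "stand_to_sit": (("living_room", "sofa"), ("kitchen", "table"), ("study", "desk")),
    "working_desk": (("study", "desk"),),
}

#: body posture required by each sustained activity class
POSTURE_OF: dict[str, str] = {
    "tooth_brushing": "upright",
    "food_chopping": "upright",
    "door_opening": "upright",
    "hair_combing": "upright",
    "picking_object": "upright",
    "pulling_blind": "upright",
    "reaching": "upright",
    "standing": "upright",
    "eating_drinking": "seated",
    "sitting": "seated",
    "working_desk": "seated",
    "lying": "lying",
    "lying_phone": "lying",
}

#: postural transitions: (from, to) -> activity class
TRANSITION_CLASSES: dict[tuple[str, str], str] = {
    ("seated", "upright"): "sit_to_stand",
    ("upright", "seated"): "stand_to_sit",
    ("lying", "seated"): "lie_to_sit",
    ("seated", "lying"): "sit_to_lie",
}

#: relative scheduling frequency of each stationary class, reflecting how
#: often daily tasks recur (postural transitions and reaching happen many
#: times per hour; grooming or meals only a few times)
CLASS_FREQUENCY_WEIGHT: dict[str, float] = {
    "tooth_brushing": 7,
    "food_chopping": 7,
    "door_opening": 30,
    "eating_drinking": 7,
    "hair_combing": 7,
    "lying": 6,
    "lying_phone": 6,
    "lie_to_sit": 30,
    "picking_object": 30,
    "pulling_blind": 5,
    "reaching": 30,
    "sitting": 15,
    "sit_to_lie": 30,
    "sit_to_stand": 40,
    "standing": 14,
    "stand_to_sit": 40,
    "working_desk": 7,
}

# Episode duration ranges (s) per class; walking durations follow from path
# length and room speed instead.
EPISODE_DURATION_S: dict[str, tuple[float, float]] = {
    "tooth_brushing": (12.0, 20.0),
    "food_chopping": (12.0, 20.0),
    "door_opening": (4.0, 6.0),
    "eating_drinking": (12.0, 20.0),
    "hair_combing": (10.0, 18.0),
    "lying": (8.0, 14.0),
    "lying_phone": (8.0, 14.0),
    "lie_to_sit": (2.0, 3.0),
    "picking_object": (3.5, 6.0),
    "pulling_blind": (8.0, 12.0),
    "reaching": (3.5, 6.0),
    "sitting": (10.0, 18.0),
    "sit_to_lie": (2.0, 3.0),
    "sit_to_stand": (2.0, 3.0),
    "standing": (5.0, 10.0),
    "stand_to_sit": (2.0, 3.0),
    "working_desk": (12.0, 20.0),
}

# ---------------------------------------------------------------------------
# Segments, sensors, joints
# ---------------------------------------------------------------------------

SEGMENTS: tuple[str, ...] = (
    "pelvis",
    "thorax",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_l",
    "forearm_r",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

#: parent segment of each non-root segment in the kinematic chain
SEGMENT_PARENT: dict[str, str] = {
    "thorax": "pelvis",
    "upper_arm_l": "thorax",
    "upper_arm_r": "thorax",
    "forearm_l": "upper_arm_l",
    "forearm_r": "upper_arm_r",
    "thigh_l": "pelvis",
    "thigh_r": "pelvis",
    "shank_l": "thigh_l",
    "shank_r": "thigh_r",
    "foot_l": "shank_l",
    "foot_r": "shank_r",
}

#: joint name -> (parent segment, child segment, euler convention)
#: ``trunk`` is thorax orientation relative to the world vertical.
JOINTS: dict[str, tuple[str, str, str]] = {
    "trunk": ("world", "thorax", "YXY"),
    "shoulder_l": ("thorax", "upper_arm_l", "YXY"),
    "shoulder_r": ("thorax", "upper_arm_r", "YXY"),
    "elbow_l": ("upper_arm_l", "forearm_l", "ZXY"),
    "elbow_r": ("upper_arm_r", "forearm_r", "ZXY"),
    "hip_l": ("pelvis", "thigh_l", "ZXY"),
    "hip_r": ("pelvis", "thigh_r", "ZXY"),
    "knee_l": ("thigh_l", "shank_l", "ZXY"),
    "knee_r": ("thigh_r", "shank_r", "ZXY"),
    "ankle_l": ("shank_l", "foot_l", "ZXY"),
    "ankle_r": ("shank_r", "foot_r", "ZXY"),
}

ANGLE_NAMES: dict[str, tuple[str, str, str]] = {
    "trunk": ("plane_of_inclination", "inclination", "axial_rotation"),
    "shoulder": ("plane_of_elevation", "elevation", "axial_rotation"),
    "elbow": ("flexion", "carrying", "axial_rotation"),
    "hip": ("flexion", "abduction", "axial_rotation"),
    "knee": ("flexion", "abduction", "axial_rotation"),
    "ankle": ("dorsi_plantar", "inversion_eversion", "axial_rotation"),
}


def joint_type(joint: str) -> str:
    return joint.rsplit("_", 1)[0] if joint != "trunk" else "trunk"


def angle_names(joint: str) -> tuple[str, str, str]:
    return ANGLE_NAMES[joint_type(joint)]


#: flat, fixed channel ordering: "<joint>.<angle>"
CHANNELS: tuple[str, ...] = tuple(
    f"{j}.{name}" for j in JOINTS for name in angle_names(j)
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}

#: anatomical plausibility bounds (deg) per angle slot of each convention,
#: used to validate synthesized motion
ANATOMICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "YXY.0": (-180.0, 180.0),
    "YXY.1": (0.0, 175.0),
    "YXY.2": (-180.0, 180.0),
    "ZXY.0": (-60.0, 160.0),
    "ZXY.1": (-80.0, 80.0),
    "ZXY.2": (-90.0, 90.0),
}


def channel_bounds(channel: str) -> tuple[float, float]:
    joint, name = channel.split(".")
    conv = JOINTS[joint][2]
    slot = angle_names(joint).index(name)
    return ANATOMICAL_BOUNDS[f"{conv}.{slot}"]
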