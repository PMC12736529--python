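"""Activity schedules: time-ordered episodes of daily-living activities.

A schedule is a contiguous tiling of the recording interval by episodes.
Stationary activities happen at a point of interest inside a room; moving
between points inserts a walking episode whose duration follows from path
length and the per-room walking speed (integrated along the path, so speed
changes as the subject crosses room boundaries).

Episode boundaries are snapped to a 10 ms grid so that the sampled label
stream's per-class dwell times equal the scheduled episode durations exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from ..taxonomy import (
    ACTIVITIES,
    ACTIVITY_ROOMS,
    CLASS_FREQUENCY_WEIGHT,
    EPISODE_DURATION_S,
    POSTURE_OF,
    TRANSITION_CLASSES,
    WALKING_CLASSES,
)
from .layout import HomeLayout

TIME_GRID_S = 0.01


def _snap(t: float) -> float:
    return round(t / TIME_GRID_S) * TIME_GRID_S


@dataclass
class Episode:
    activity: str
    start: float
    end: float
    room: str
    point: np.ndarray                  # where the episode happens / ends (m)
    path_from: np.ndarray | None = None  # walking only: start of the path

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ActivitySchedule:
    episodes: list[Episode]
    subject_id: str
    layout: HomeLayout

    def __post_init__(self) -> None:
        self.validate()

    @property
    def duration(self) -> float:
        return self.episodes[-1].end

    def validate(self) -> None:
        prev_end = 0.0
        for ep in self.episodes:
            if ep.activity not in ACTIVITIES:
                raise ValueError(f"unknown activity class {ep.activity!r}")
            if ep.end <= ep.start:
                raise ValueError("episode must have positive duration")
            if abs(ep.start - prev_end) > 1e-9:
                raise ValueError("episodes must be time-ordered and contiguous")
            prev_end = ep.end
            if ep.activity not in WALKING_CLASSES:
                if not self.layout.rooms[ep.room].covers(Point(ep.point)):
                    raise ValueError(
                        f"{ep.activity} anchor point lies outside room {ep.room!r}"
                    )

    def label_codes(self, fs_hz: float) -> np.ndarray:
        """Per-sample activity codes on the fs_hz grid covering [0, duration)."""
        n = int(round(self.duration * fs_hz))
        t = (np.arange(n) + 0.5) / fs_hz  # sample-interval midpoints
        starts = np.array([ep.start for ep in self.episodes])
        idx = np.searchsorted(starts, t, side="right") - 1
        codes = np.array([ACTIVITIES.index(ep.activity) for ep in self.episodes])
        return codes[idx]

    def class_durations(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for ep in self.episodes:
            out[ep.activity] = out.get(ep.activity, 0.0) + ep.duration
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "episodes": [
                    {
                        "activity": ep.activity,
                        "start": round(ep.start, 6),
                        "end": round(ep.end, 6),
                        "room": ep.room,
                        "point": [float(ep.point[0]), float(ep.point[1])],
                        "path_from": None
                        if ep.path_from is None
                        else [float(ep.path_from[0]), float(ep.path_from[1])],
                    }
                    for ep in self.episodes
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str, layout: HomeLayout) -> "ActivitySchedule":
        obj = json.loads(text)
        eps = [
            Episode(
                activity=d["activity"],
                start=float(d["start"]),
                end=float(d["end"]),
                room=d["room"],
                point=np.asarray(d["point"], float),
                path_from=None if d["path_from"] is None else np.asarray(d["path_from"], float),
            )
            for d in obj["episodes"]
        ]
        return cls(episodes=eps, subject_id=obj["subject_id"], layout=layout)


def integrate_walk(
    layout: HomeLayout, p0: np.ndarray, p1: np.ndarray, dt: float = TIME_GRID_S
) -> np.ndarray:
    """Positions along the straight path p0 -> p1, stepped at dt with the
    walking speed of whichever room the subject currently occupies.

    Returns an (n, 2) array; sample j is the position at j*dt, sample 0 is p0
    and the last sample is within one step of p1.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    if length < 1e-12:
        return p0[None, :]
    direction = (p1 - p0) / length
    positions = [p0]
    s = 0.0
    while s < length - 1e-12:
        room = layout.room_of(positions[-1])
        v = layout.room_speeds.get(room, 0.9)
        s = min(length, s + v * dt)
        positions.append(p0 + s * direction)
    return np.asarray(positions)


def walk_duration(layout: HomeLayout, p0: np.ndarray, p1: np.ndarray) -> float:
    n = integrate_walk(layout, p0, p1).shape[0]
    return _snap((n - 1) * TIME_GRID_S)


def generate_schedule(
    layout: HomeLayout,
    duration_s: float,
    seed: int,
    subject_id: str = "s01",
) -> ActivitySchedule:
    """Random schedule covering [0, duration_s] with all 19 classes present.

    Sustained activities are drawn with realistic relative frequencies and
    connected by a postural state machine (upright / seated / lying): moving
    to a new point of interest requires standing up first and inserts a
    walking episode (the two walking classes alternate), and seated or lying
    activities are entered through their natural transitions (stand-to-sit,
    sit-to-lie, ...). A first pass visits every sustained class once in random
    order; weighted draws then fill the remaining time. Raises if duration_s
    cannot fit one episode of each class.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5C1D]))

    posture_classes = sorted(POSTURE_OF)
    order = list(posture_classes)
    rng.shuffle(order)
    n_extra = int(duration_s / 3.0) + 40
    weights = np.array([CLASS_FREQUENCY_WEIGHT[c] for c in posture_classes], float)
    weights /= weights.sum()
    extra = [str(c) for c in rng.choice(posture_classes, size=n_extra, p=weights)]

    episodes: list[Episode] = []
    t = 0.0
    state = "upright"
    cur_point: np.ndarray | None = None
    cur_room: str | None = None

    def jittered_point(room: str, poi: str) -> np.ndarray:
        base = layout.points_of_interest[poi][1]
        for _ in range(8):
            cand = base + rng.uniform(-0.25, 0.25, size=2)
            if layout.rooms[room].contains(Point(cand)):
                return cand
        return base.copy()

    def emit(activity: str, room: str, point: np.ndarray, path_from=None) -> None:
        nonlocal t
        if activity in WALKING_CLASSES:
            dur = walk_duration(layout, path_from, point)
            if dur <= 0:
                return
        else:
            lo, hi = EPISODE_DURATION_S[activity]
            dur = _snap(float(rng.uniform(lo, hi)))
        episodes.append(Episode(activity, t, _snap(t + dur), room, point, path_from))
        t = _snap(t + dur)

    def goto_posture(target: str) -> None:
        nonlocal state
        while state != target:
            step = target if (state, target) in TRANSITION_CLASSES else "seated"
            emit(TRANSITION_CLASSES[(state, step)], cur_room, cur_point)
            state = step

    for k, activity in enumerate(order + extra):
        in_coverage_pass = k < len(order)
        options = ACTIVITY_ROOMS[activity]
        here = [o for o in options if o[0] == cur_room]
        if here and rng.random() < 0.65:  # subjects cluster tasks by room
            room, poi = here[int(rng.integers(0, len(here)))]
        else:
            room, poi = options[int(rng.integers(0, len(options)))]
        point = jittered_point(room, poi)

        if cur_point is None:
            cur_point, cur_room = point, room
        elif np.hypot(*(point - cur_point)) > 0.05:
            goto_posture("upright")
            # most walks are plain walking; phone-walking is the rarer variant
            wclass = WALKING_CLASSES[int(rng.random() < 0.35)]
            emit(wclass, room, point, path_from=cur_point)
            cur_point, cur_room = point, room

        goto_posture(POSTURE_OF[activity])
        emit(activity, room, point)
        if t >= duration_s and not in_coverage_pass:
            break

    # trim the tail exactly to duration_s
    while episodes and episodes[-1].start >= duration_s - 1e-9:
        episodes.pop()
    if episodes:
        last = episodes[-1]
        episodes[-1] = Episode(
            last.activity, last.start, _snap(duration_s), last.room, last.point, last.path_from
        )

    covered = {ep.activity for ep in episodes}
    if len(covered) < len(ACTIVITIES):
        raise ValueError(
            f"duration {duration_s} s is too short to fit one episode of each "
            f"of the {len(ACTIVITIES)} activity classes"
        )
    return ActivitySchedule(episodes=episodes, subject_id=subject_id, layout=layout)
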