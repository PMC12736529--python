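"""Single-bedroom apartment layout: room polygons, UWB anchors, points of interest.

The apartment is a 12 m x 8 m rectangle tiled by five rooms (kitchen, living
room, study, bathroom, bedroom). Interior wall positions are jittered per
seed so no two generated homes are identical; anchors sit on the exterior
walls at a configured height. Room polygons partition the walkable area, so
per-room occupancy times conserve total recording time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

ANCHOR_HEIGHT_M = 1.8

ROOM_NAMES = ("living_room", "kitchen", "bedroom", "bathroom", "study")

#: default walking speed per room (m/s); reflects how cluttered/confined each
#: space is (fastest in the open living room, slowest in the bathroom)
DEFAULT_ROOM_SPEEDS = {
    "living_room": 1.00,
    "kitchen": 0.98,
    "study": 0.94,
    "bedroom": 0.79,
    "bathroom": 0.78,
}


@dataclass
class HomeLayout:
    """Floor plan: named room polygons, labeled anchors, points of interest."""

    rooms: dict[str, Polygon]
    anchors: dict[str, np.ndarray]  # label -> (x, y, z) in m
    points_of_interest: dict[str, tuple[str, np.ndarray]]  # name -> (room, (x, y))
    room_speeds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ROOM_SPEEDS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.anchors) < 4:
            raise ValueError("a layout needs at least 4 UWB anchors")
        for name, poly in self.rooms.items():
            if not poly.is_simple or not poly.is_valid:
                raise ValueError(f"room polygon {name!r} is not simple")
        names = list(self.rooms)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self.rooms[a].intersection(self.rooms[b])
                if inter.area > 1e-9:
                    raise ValueError(f"rooms {a!r} and {b!r} overlap")
        for poi, (room, xy) in self.points_of_interest.items():
            inside = [n for n, p in self.rooms.items() if p.contains(Point(xy))]
            if inside != [room]:
                raise ValueError(
                    f"point of interest {poi!r} must lie inside exactly its room "
                    f"{room!r}, found {inside}"
                )

    @property
    def anchor_array(self) -> np.ndarray:
        """Anchor planar coordinates, shape (n_anchors, 2), in label order."""
        return np.array([self.anchors[k][:2] for k in sorted(self.anchors)])

    def room_of(self, xy) -> str:
        """Room containing a planar point; boundary points go to the first
        covering room in insertion order; outside -> ``"none"``."""
        pt = Point(xy)
        for name, poly in self.rooms.items():
            if poly.covers(pt):
                return name
        return "none"

    def rooms_of(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized room assignment for an (n, 2) array of planar points."""
        pts = shapely.points(np.asarray(xy, dtype=float))
        out = np.full(len(pts), "none", dtype=object)
        unassigned = np.ones(len(pts), dtype=bool)
        for name, poly in self.rooms.items():
            hit = unassigned & shapely.covers(poly, pts)
            out[hit] = name
            unassigned &= ~hit
        return out

    def to_json(self) -> str:
        obj = {
            "rooms": {n: list(map(list, p.exterior.coords)) for n, p in self.rooms.items()},
            "anchors": {n: list(map(float, a)) for n, a in self.anchors.items()},
            "points_of_interest": {
                n: {"room": r, "xy": list(map(float, xy))}
                for n, (r, xy) in self.points_of_interest.items()
            },
            "room_speeds": self.room_speeds,
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HomeLayout":
        obj = json.loads(text)
        return cls(
            rooms={n: Polygon(c) for n, c in obj["rooms"].items()},
            anchors={n: np.asarray(a, float) for n, a in obj["anchors"].items()},
            points_of_interest={
                n: (d["room"], np.asarray(d["xy"], float))
                for n, d in obj["points_of_interest"].items()
            },
            room_speeds={n: float(v) for n, v in obj["room_speeds"].items()},
        )


def generate_layout(seed: int) -> HomeLayout:
    """Deterministically generate a 5-room apartment with 5 wall anchors.

    Interior walls are jittered by up to +-0.3 m around the nominal plan.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A]))
    j = rng.uniform(-0.3, 0.3, size=4)
    w, h = 12.0, 8.0
    x1 = 6.0 + j[0]   # living/kitchen divider
    x2 = 6.0 + j[1]   # bedroom/bathroom divider
    x3 = 9.0 + j[2]   # bathroom/study divider
    y1 = 4.0 + j[3]   # lower/upper divider

    def rect(xa, ya, xb, yb):
        return Polygon([(xa, ya), (xb, ya), (xb, yb), (xa, yb)])

    rooms = {
        "living_room": rect(0, 0, x1, y1),
        "kitchen": rect(x1, 0, w, y1),
        "bedroom": rect(0, y1, x2, h),
        "bathroom": rect(x2, y1, x3, h),
        "study": rect(x3, y1, w, h),
    }
    anchors = {
        "a1": np.array([0.0, 0.0, ANCHOR_HEIGHT_M]),
        "a2": np.array([w, 0.0, ANCHOR_HEIGHT_M]),
        "a3": np.array([w, h, ANCHOR_HEIGHT_M]),
        "a4": np.array([0.0, h, ANCHOR_HEIGHT_M]),
        "a5": np.array([w / 2, h, ANCHOR_HEIGHT_M]),
    }

    def in_room(room, fx, fy):
        xa, ya, xb, yb = rooms[room].bounds
        return np.array([xa + fx * (xb - xa), ya + fy * (yb - ya)])

    pois = {
        "sofa": ("living_room", in_room("living_room", 0.3, 0.5)),
        "balcony_door": ("living_room", in_room("living_room", 0.08, 0.85)),
        "table": ("kitchen", in_room("kitchen", 0.5, 0.45)),
        "bench": ("kitchen", in_room("kitchen", 0.8, 0.2)),
        "fridge": ("kitchen", in_room("kitchen", 0.85, 0.8)),
        "bed": ("bedroom", in_room("bedroom", 0.35, 0.55)),
        "window": ("bedroom", in_room("bedroom", 0.1, 0.9)),
        "mirror": ("bathroom", in_room("bathroom", 0.5, 0.85)),
        "door": ("bathroom", in_room("bathroom", 0.5, 0.12)),
        "desk": ("study", in_room("study", 0.7, 0.6)),
        "shelf": ("study", in_room("study", 0.9, 0.15)),
    }
    return HomeLayout(rooms=rooms, anchors=anchors, points_of_interest=pois)
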