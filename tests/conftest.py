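import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hometwin.synth import generate_layout, generate_schedule, synthesize_motion

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return generate_layout(0)


@pytest.fixture(scope="session")
def schedule(layout):
    return generate_schedule(layout, 300.0, seed=5, subject_id="s01")


@pytest.fixture(scope="session")
def truth(schedule):
    return synthesize_motion(schedule, seed=5)


def ray_casting_contains(polygon_coords, point) -> bool:
    """Independent point-in-polygon oracle (even-odd ray casting)."""
    x, y = point
    inside = False
    pts = list(polygon_coords)
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xc > x:
                inside = not inside
    return inside


def wrap_deg(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0
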