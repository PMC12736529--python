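import numpy as np
import pytest

from hometwin import localization as loc
from hometwin.synth.sensors import TdoaFrames, true_range_differences

from conftest import ray_casting_contains


def _grid_refine_oracle(deltas, anchors, lo, hi, levels=6):
    """Brute-force multilateration: coarse grid search with refinement."""
    best = None
    center = (np.asarray(lo) + np.asarray(hi)) / 2.0
    half = (np.asarray(hi) - np.asarray(lo)) / 2.0
    for _ in range(levels):
        xs = np.linspace(center[0] - half[0], center[0] + half[0], 21)
        ys = np.linspace(center[1] - half[1], center[1] + half[1], 21)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        resid = true_range_differences(pts, anchors) - deltas
        cost = (resid**2).sum(axis=1)
        best = pts[np.argmin(cost)]
        center = best
        half = half / 8.0
    return best


@pytest.fixture(scope="module")
def anchors():
    return np.array([[0.0, 0.0], [12.0, 0.0], [12.0, 8.0], [0.0, 8.0], [6.0, 8.0]])


class TestMultilaterate:
    def test_noiseless_recovers_position_and_matches_grid_oracle(self, anchors):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform([0.5, 0.5], [11.5, 7.5])
            deltas = true_range_differences(p[None, :], anchors)[0]
            est, rms, ok = loc.multilaterate(deltas, anchors, anchors.mean(axis=0))
            assert ok and rms < 1e-9
            assert np.linalg.norm(est - p) < 1e-6
            oracle = _grid_refine_oracle(deltas, anchors, [0, 0], [12, 8])
            assert np.linalg.norm(est - oracle) < 1e-3

    def test_symmetric_square_centroid(self):
        square = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 2.0]])
        center = square.mean(axis=0)
        deltas = true_range_differences(center[None, :], square)[0]
        assert np.allclose(deltas, 0.0)
        est, _, ok = loc.multilaterate(deltas, square, center + [0.1, -0.05])
        assert ok and np.linalg.norm(est - center) < 1e-6

    def test_median_error_within_30cm_at_12cm_ranging_noise(self, anchors):
        rng = np.random.default_rng(1)
        pts = rng.uniform([0.5, 0.5], [11.5, 7.5], size=(1000, 2))
        deltas = true_range_differences(pts, anchors) + rng.normal(0, 0.12, (1000, 4))
        errs = np.empty(1000)
        guess = anchors.mean(axis=0)
        for k in range(1000):
            est, _, _ = loc.multilaterate(deltas[k], anchors, guess)
            errs[k] = np.linalg.norm(est - pts[k])
        assert np.median(errs) < 0.30

    def test_error_degrades_monotonically_with_noise(self, anchors):
        rng = np.random.default_rng(2)
        pts = rng.uniform([1, 1], [11, 7], size=(200, 2))
        medians = []
        for sd in (0.02, 0.12, 0.5):
            deltas = true_range_differences(pts, anchors) + rng.normal(0, sd, (200, 4))
            errs = [
                np.linalg.norm(loc.multilaterate(deltas[k], anchors, pts[k])[0] - pts[k])
                for k in range(200)
            ]
            medians.append(np.median(errs))
        assert medians[0] < medians[1] < medians[2]

    def test_too_few_range_differences_rejected(self, anchors):
        with pytest.raises(ValueError):
            loc.multilaterate(np.array([1.0, 2.0]), anchors[:3], np.zeros(2))


def _traj(positions, rate=100.0):
    n = positions.shape[0]
    return loc.Trajectory(
        times=np.arange(n) / rate,
        positions=np.asarray(positions, float),
        rooms=np.full(n, "none", dtype=object),
        quality=np.ones(n, dtype=bool),
        rate_hz=rate,
    )


class TestSpeedAndDistance:
    def test_stationary_speed_zero(self):
        tr = _traj(np.tile([1.0, 2.0], (100, 1)))
        assert np.allclose(loc.speed_instantaneous(tr), 0.0)

    def test_constant_velocity(self):
        t = np.arange(300) / 100.0
        tr = _traj(np.column_stack([t * 1.0, np.zeros_like(t)]))
        v = loc.speed_instantaneous(tr)
        assert np.allclose(v, 1.0, atol=1e-12)

    def test_speed_matches_bruteforce_pairwise(self):
        rng = np.random.default_rng(4)
        pos = np.cumsum(rng.normal(0, 0.01, (500, 2)), axis=0)
        tr = _traj(pos)
        v = loc.speed_instantaneous(tr)
        lag = 20
        expected = np.linalg.norm(pos[lag:] - pos[:-lag], axis=1) / 0.2
        assert np.max(np.abs(v[lag:] - expected)) < 1e-12

    def test_square_loop_distance_is_perimeter(self):
        side = np.linspace(0, 2, 21)[:-1]
        loop = np.concatenate([
            np.column_stack([side, np.zeros_like(side)]),
            np.column_stack([np.full_like(side, 2.0), side]),
            np.column_stack([2.0 - side, np.full_like(side, 2.0)]),
            np.column_stack([np.zeros_like(side), 2.0 - side]),
            [[0.0, 0.0]],
        ])
        assert loc.total_distance(_traj(loop)) == pytest.approx(8.0, abs=1e-12)

    def test_single_sample_distance_zero(self):
        assert loc.total_distance(_traj(np.array([[1.0, 1.0]]))) == 0.0

    def test_lowpass_suppresses_noise_inflated_distance(self, layout):
        """A noisy stationary tag accumulates spurious path length; the
        configured 0.5 Hz smoothing removes almost all of it."""
        rng = np.random.default_rng(5)
        n = 3000
        pos = np.array([3.0, 2.0]) + rng.normal(0, 0.1, (n, 2))
        raw = loc.total_distance(_traj(pos))
        from scipy.signal import butter, filtfilt

        b, a = butter(2, 0.5 / 50.0)
        smooth = filtfilt(b, a, pos, axis=0)
        filtered = loc.total_distance(_traj(smooth))
        assert filtered < 0.05 * raw


class TestOccupancy:
    def test_single_room_gets_all_time(self, layout):
        poi = layout.points_of_interest["desk"][1]
        pos = np.tile(poi, (1000, 1))
        tr = loc.Trajectory(np.arange(1000) / 100.0, pos, layout.rooms_of(pos),
                            np.ones(1000, bool))
        occ = loc.occupancy(tr, layout)
        total = sum(occ.room_time_min.values())
        assert occ.room_time_min["study"] == pytest.approx(total)

    def test_room_times_conserve_duration(self, truth, layout_from_truth=None):
        lay = truth.layout
        tr = loc.Trajectory(truth.times, truth.trajectory, truth.rooms,
                            np.ones(truth.times.size, bool))
        occ = loc.occupancy(tr, lay)
        assert sum(occ.room_time_min.values()) * 60.0 == pytest.approx(
            truth.times.size / 100.0, abs=1e-9
        )

    def test_room_assignment_matches_ray_casting_oracle(self, layout):
        rng = np.random.default_rng(6)
        pts = rng.uniform([0.01, 0.01], [11.99, 7.99], size=(10_000, 2))
        assigned = layout.rooms_of(pts)
        for name, poly in layout.rooms.items():
            coords = list(poly.exterior.coords)
            sel = assigned == name
            # strict-interior points must agree with the ray-casting oracle
            inside = np.array([ray_casting_contains(coords, p) for p in pts])
            on_edge = np.array([
                abs(p[0] - poly.bounds[0]) < 1e-9 or abs(p[0] - poly.bounds[2]) < 1e-9
                or abs(p[1] - poly.bounds[1]) < 1e-9 or abs(p[1] - poly.bounds[3]) < 1e-9
                for p in pts
            ])
            mism = (inside != sel) & ~on_edge
            assert not mism.any(), name

    def test_heatmap_mass_equals_duration(self, layout):
        rng = np.random.default_rng(7)
        pos = rng.uniform([0, 0], [12, 8], (2000, 2))
        tr = loc.Trajectory(np.arange(2000) / 100.0, pos, layout.rooms_of(pos),
                            np.ones(2000, bool))
        occ = loc.occupancy(tr, layout)
        assert occ.heatmap.sum() == pytest.approx(20.0, abs=1e-9)


class TestTrajectoryRecovery:
    def test_room_speeds_recovered_from_truth_noiseless(self, truth):
        """Configured per-room walking speeds recovered within 3% from the
        noiseless trajectory (no smoothing)."""
        from hometwin.taxonomy import ACTIVITIES, WALKING_CLASSES

        lay = truth.layout
        tr = loc.Trajectory(truth.times, truth.trajectory, truth.rooms,
                            np.ones(truth.times.size, bool))
        walking = np.isin(np.asarray(ACTIVITIES, object)[truth.labels], WALKING_CLASSES)
        occ = loc.occupancy(tr, lay, walking_mask=walking)
        for room, speed in occ.room_walking_speed.items():
            if np.isfinite(speed):
                assert speed == pytest.approx(lay.room_speeds[room], rel=0.03), room

    def test_full_uwb_chain_speeds_within_15pct_at_12cm_noise(self, truth):
        from hometwin.synth import simulate_uwb
        from hometwin.taxonomy import ACTIVITIES, WALKING_CLASSES

        lay = truth.layout
        frames = simulate_uwb(truth, noise_sd_m=0.12, seed=8)
        traj = loc.solve_trajectory(frames, lay)
        walking = np.isin(np.asarray(ACTIVITIES, object)[truth.labels], WALKING_CLASSES)
        n = min(traj.times.size, walking.size)
        traj = loc.Trajectory(traj.times[:n], traj.positions[:n], traj.rooms[:n],
                              traj.quality[:n])
        occ = loc.occupancy(traj, lay, walking_mask=walking[:n])
        for room, speed in occ.room_walking_speed.items():
            if np.isfinite(speed):
                assert speed == pytest.approx(lay.room_speeds[room], rel=0.15), room
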