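"""UWB TDOA localization and spatial mobility metrics.

Planar tag position is estimated per frame by nonlinear least squares on the
range differences (Levenberg-Marquardt, warm-started at the previous
solution), resampled to the common 100 Hz grid, and smoothed with a
zero-phase second-order low-pass (default 0.5 Hz) before any speed or
distance is derived — raw UWB jitter would otherwise inflate path length.

Derived metrics mirror a home-mobility study's outcomes: instantaneous speed
as the displacement-time ratio over 0.2 s, total distance as the sum of
instantaneous displacements, per-room cumulative occupancy time, a dwell-time
heatmap on a 0.25 m grid, and per-room mean walking speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .synth.layout import HomeLayout
from .synth.sensors import TdoaFrames, true_range_differences

COMMON_RATE_HZ = 100.0
SPEED_INTERVAL_S = 0.2
POSITION_LOWPASS_HZ = 0.5
HEATMAP_CELL_M = 0.25


def multilaterate(
    deltas: np.ndarray,
    anchors: np.ndarray,
    init: np.ndarray,
    max_nfev: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """Solve one TDOA frame for planar position.

    Returns (position, rms_residual, converged). Requires >= 3 range
    differences for a 2-D solve.
    """
    deltas = np.asarray(deltas, float)
    if deltas.size < 3:
        raise ValueError("need at least 3 range differences for a 2-D solve")

    def resid(p):
        return true_range_differences(p[None, :], anchors)[0] - deltas

    sol = least_squares(resid, np.asarray(init, float), method="lm", max_nfev=max_nfev)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return sol.x, rms, bool(sol.success)


@dataclass
class Trajectory:
    """Planar tag positions with per-sample room assignment and quality flag."""

    times: np.ndarray          # (n,), s
    positions: np.ndarray      # (n, 2), m
    rooms: np.ndarray          # (n,) room names
    quality: np.ndarray        # (n,) bool, False = carried-forward/bad solve
    rate_hz: float = COMMON_RATE_HZ


def solve_trajectory(
    frames: TdoaFrames,
    layout: HomeLayout,
    rate_hz: float = COMMON_RATE_HZ,
    lowpass_hz: float | None = POSITION_LOWPASS_HZ,
    residual_gate_m: float = 1.0,
) -> Trajectory:
    """Per-frame multilateration, 100 Hz linear resampling, smoothing, rooms.

    Non-converged or high-residual frames are flagged and carried forward.
    """
    anchors = layout.anchor_array
    n = len(frames)
    raw = np.empty((n, 2))
    good = np.ones(n, dtype=bool)
    guess = anchors.mean(axis=0)
    for k in range(n):
        pos, rms, ok = multilaterate(frames.deltas[k], anchors, guess)
        if not ok or rms > residual_gate_m:
            good[k] = False
            raw[k] = raw[k - 1] if k > 0 else guess
        else:
            raw[k] = pos
            guess = pos
    # uniform 100 Hz grid across the frame span
    k1 = int(np.floor(round(frames.times[-1] * rate_hz, 9)))
    k0 = int(np.ceil(round(frames.times[0] * rate_hz, 9)))
    grid = np.arange(k0, k1 + 1) / rate_hz
    pos = np.column_stack(
        [np.interp(grid, frames.times, raw[:, i]) for i in range(2)]
    )
    if lowpass_hz and pos.shape[0] > 30:
        b, a = butter(2, lowpass_hz / (rate_hz / 2.0))
        pos = filtfilt(b, a, pos, axis=0)
    quality = np.interp(grid, frames.times, good.astype(float)) >= 1.0 - 1e-9
    rooms = layout.rooms_of(pos)
    return Trajectory(times=grid, positions=pos, rooms=rooms, quality=quality, rate_hz=rate_hz)


def speed_instantaneous(traj: Trajectory, interval_s: float = SPEED_INTERVAL_S) -> np.ndarray:
    """Speed at t as displacement over the preceding ``interval_s`` window.

    The first ``interval_s`` of samples reuses the earliest full window.
    """
    lag = int(round(interval_s * traj.rate_hz))
    if traj.positions.shape[0] <= lag:
        raise ValueError(f"need more than {interval_s} s of data")
    disp = np.linalg.norm(traj.positions[lag:] - traj.positions[:-lag], axis=1)
    v = disp / interval_s
    return np.concatenate([np.full(lag, v[0]), v])


def total_distance(traj: Trajectory) -> float:
    """Sum of instantaneous displacements over quality-good samples."""
    if traj.positions.shape[0] < 2:
        return 0.0
    ok = traj.quality[:-1] & traj.quality[1:]
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    return float(steps[ok].sum())


@dataclass
class OccupancySummary:
    room_time_min: dict[str, float]
    total_distance_m: float
    room_walking_speed: dict[str, float]     # mean m/s over walking samples
    heatmap: np.ndarray                      # dwell s per cell
    heatmap_origin: tuple[float, float]
    heatmap_cell_m: float = HEATMAP_CELL_M


def occupancy(
    traj: Trajectory,
    layout: HomeLayout,
    walking_mask: np.ndarray | None = None,
    cell_m: float = HEATMAP_CELL_M,
) -> OccupancySummary:
    """Per-room cumulative time, dwell heatmap, distance, per-room walk speed."""
    dt = 1.0 / traj.rate_hz
    names = list(layout.rooms) + ["none"]
    room_time = {r: float(np.sum(traj.rooms == r)) * dt / 60.0 for r in names}

    xmin, ymin = traj.positions.min(axis=0)
    minx = min(xmin, min(p.bounds[0] for p in layout.rooms.values()))
    miny = min(ymin, min(p.bounds[1] for p in layout.rooms.values()))
    maxx = max(traj.positions[:, 0].max(), max(p.bounds[2] for p in layout.rooms.values()))
    maxy = max(traj.positions[:, 1].max(), max(p.bounds[3] for p in layout.rooms.values()))
    nx = int(np.ceil((maxx - minx) / cell_m)) + 1
    ny = int(np.ceil((maxy - miny) / cell_m)) + 1
    ix = np.clip(((traj.positions[:, 0] - minx) / cell_m).astype(int), 0, nx - 1)
    iy = np.clip(((traj.positions[:, 1] - miny) / cell_m).astype(int), 0, ny - 1)
    heat = np.zeros((ny, nx))
    np.add.at(heat, (iy, ix), dt)

    speeds = speed_instantaneous(traj)
    walk_speed: dict[str, float] = {}
    if walking_mask is not None:
        # keep only samples whose whole displacement window lies within walking,
        # so stationary time never leaks into the ratio
        lag = int(round(SPEED_INTERVAL_S * traj.rate_hz))
        full = walking_mask.copy()
        full[lag:] &= walking_mask[:-lag]
        full[:lag] = False
        for r in layout.rooms:
            sel = full & (traj.rooms == r)
            walk_speed[r] = float(speeds[sel].mean()) if sel.any() else float("nan")

    return OccupancySummary(
        room_time_min=room_time,
        total_distance_m=total_distance(traj),
        room_walking_speed=walk_speed,
        heatmap=heat,
        heatmap_origin=(float(minx), float(miny)),
        heatmap_cell_m=cell_m,
    )
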