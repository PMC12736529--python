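"""End-to-end run orchestration with per-stage artifacts and a manifest.

Stages (synth -> orientation -> localization -> classify -> summary -> stats)
read their inputs from the run directory and write tidy CSV/JSON artifacts,
so any later stage can be re-run from stored intermediates and reproduce
byte-identical outputs. All randomness flows from the config's single root
seed through named substreams.

Artifact sizes scale with recording length; the default full-cohort analysis
drives the library directly (see the analysis scripts), while this runner is
sized for demonstration and reproducibility checks on shorter recordings.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import localization as loc
from . import orientation as ori
from . import stats  # noqa: F401  (re-exported for report consumers)
from . import summary as summ
from .bvh import export_pose_stream
from .config import RunConfig
from .orientation import QuaternionStream
from .synth import (
    ActivitySchedule,
    CalibrationPoses,
    HomeLayout,
    generate_layout,
    generate_schedule,
    simulate_imu,
    simulate_uwb,
    synthesize_motion,
)
from .synth.sensors import TdoaFrames
from .taxonomy import ACTIVITIES, SEGMENTS, WALKING_CLASSES

log = logging.getLogger("hometwin")

STAGES = ("simulate", "calibrate", "angles", "localize", "classify", "summarize")

_F = "%.6f"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_F)


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    """Ground truth + raw sensor observations for every subject."""
    run_dir.mkdir(parents=True, exist_ok=True)
    layout = generate_layout(cfg.root_seed)
    (run_dir / "layout.json").write_text(layout.to_json())
    cfg.save(run_dir / "config.json")

    sched_seeds = cfg.subject_seeds("schd")
    motion_seeds = cfg.subject_seeds("motn")
    imu_seeds = cfg.subject_seeds("imu_")
    uwb_seeds = cfg.subject_seeds("uwb_")

    for i, sid in enumerate(cfg.subject_ids()):
        sdir = run_dir / sid
        sdir.mkdir(exist_ok=True)
        schedule = generate_schedule(layout, cfg.duration_s, sched_seeds[i], sid)
        (sdir / "schedule.json").write_text(schedule.to_json())
        truth = synthesize_motion(schedule, seed=motion_seeds[i], fs_hz=cfg.common_hz)

        tdf = pd.DataFrame(truth.joint_angles, columns=list(truth_channel_names()))
        tdf.insert(0, "time_s", truth.times)
        _write_csv(tdf, sdir / "truth_angles.csv")
        meta = pd.DataFrame(
            {
                "time_s": truth.times,
                "x_m": truth.trajectory[:, 0],
                "y_m": truth.trajectory[:, 1],
                "activity": truth.label_names(),
                "room": truth.rooms,
            }
        )
        _write_csv(meta, sdir / "truth_state.csv")

        streams, poses = simulate_imu(
            truth,
            noise_deg=cfg.imu_noise_deg,
            seed=imu_seeds[i],
            rate_hz=cfg.imu_hz,
            drift_deg_per_min=cfg.imu_drift_deg_per_min,
            pose_noise_deg=cfg.pose_noise_deg,
        )
        frames = []
        for name in SEGMENTS:
            s = streams[name]
            df = pd.DataFrame(s.quat_wxyz, columns=["qw", "qx", "qy", "qz"])
            df.insert(0, "time_s", s.times)
            df.insert(1, "sensor", name)
            frames.append(df)
        _write_csv(pd.concat(frames, ignore_index=True), sdir / "imu_quaternions.csv")
        pose_obj = {
            "pose1": {k: list(map(float, v)) for k, v in poses.pose1.items()},
            "pose2": {k: list(map(float, v)) for k, v in poses.pose2.items()},
        }
        (sdir / "calibration_poses.json").write_text(json.dumps(pose_obj, indent=1, sort_keys=True))

        tdoa = simulate_uwb(truth, layout, cfg.uwb_noise_m, uwb_seeds[i], cfg.uwb_hz)
        cols = {f"d{i + 2}1_m": tdoa.deltas[:, i] for i in range(tdoa.deltas.shape[1])}
        _write_csv(pd.DataFrame({"time_s": tdoa.times, **cols}), sdir / "uwb_tdoa.csv")
    log.info("simulate: %d subjects written to %s", cfg.n_subjects, run_dir)


def truth_channel_names() -> tuple[str, ...]:
    from .taxonomy import CHANNELS

    return CHANNELS


def _load_layout(run_dir: Path) -> HomeLayout:
    return HomeLayout.from_json((run_dir / "layout.json").read_text())


# ---------------------------------------------------------------------------
# stage: calibrate
# ---------------------------------------------------------------------------


def stage_calibrate(cfg: RunConfig, run_dir: Path) -> None:
    """TRIAD sensor-to-segment calibration from the stored pose readings."""
    for sid in cfg.subject_ids():
        sdir = run_dir / sid
        obj = json.loads((sdir / "calibration_poses.json").read_text())
        out = {}
        for seg in SEGMENTS:
            cal = ori.calibrate_segment(
                np.asarray(obj["pose1"][seg]), np.asarray(obj["pose2"][seg]), seg
            )
            out[seg] = {
                "matrix": np.round(cal.matrix, 12).tolist(),
                "residual_deg": cal.residual_deg,
            }
        (sdir / "calibration.json").write_text(json.dumps(out, indent=1, sort_keys=True))


def _load_calibrations(sdir: Path) -> dict[str, ori.MountingCalibration]:
    obj = json.loads((sdir / "calibration.json").read_text())
    return {
        seg: ori.MountingCalibration(seg, np.asarray(d["matrix"]), d["residual_deg"])
        for seg, d in obj.items()
    }


# ---------------------------------------------------------------------------
# stage: angles
# ---------------------------------------------------------------------------


def stage_angles(cfg: RunConfig, run_dir: Path) -> None:
    """Recover joint angles from stored quaternion streams + calibration."""
    for sid in cfg.subject_ids():
        sdir = run_dir / sid
        raw = pd.read_csv(sdir / "imu_quaternions.csv")
        streams = {}
        for seg, g in raw.groupby("sensor"):
            streams[seg] = QuaternionStream(
                seg,
                g["time_s"].to_numpy(),
                g[["qw", "qx", "qy", "qz"]].to_numpy(),
                cfg.imu_hz,
            ).canonicalized()
        cals = _load_calibrations(sdir)
        rec = ori.recover_joint_angles(
            streams, cals, rate_hz=cfg.common_hz, lowpass_hz=cfg.angle_lowpass_hz
        )
        df = pd.DataFrame(rec.angles, columns=list(rec.channels))
        df.insert(0, "time_s", rec.times)
        _write_csv(df, sdir / "joint_angles.csv")


# ---------------------------------------------------------------------------
# stage: localize
# ---------------------------------------------------------------------------


def stage_localize(cfg: RunConfig, run_dir: Path) -> None:
    """Trajectories and occupancy summaries from stored TDOA frames."""
    layout = _load_layout(run_dir)
    occ_rows = []
    for sid in cfg.subject_ids():
        sdir = run_dir / sid
        df = pd.read_csv(sdir / "uwb_tdoa.csv")
        frames = TdoaFrames(
            times=df["time_s"].to_numpy(),
            deltas=df[[c for c in df.columns if c.startswith("d")]].to_numpy(),
            anchor_labels=tuple(sorted(layout.anchors)),
        )
        traj = loc.solve_trajectory(
            frames, layout, rate_hz=cfg.common_hz, lowpass_hz=cfg.position_lowpass_hz
        )
        tdf = pd.DataFrame(
            {
                "time_s": traj.times,
                "x_m": traj.positions[:, 0],
                "y_m": traj.positions[:, 1],
                "room": traj.rooms,
                "quality": traj.quality.astype(int),
            }
        )
        _write_csv(tdf, sdir / "trajectory.csv")

        state = pd.read_csv(sdir / "truth_state.csv")
        walking = np.isin(state["activity"].to_numpy(), WALKING_CLASSES)
        n = min(len(traj.times), walking.size)
        traj_n = loc.Trajectory(
            traj.times[:n], traj.positions[:n], traj.rooms[:n], traj.quality[:n], traj.rate_hz
        )
        occ = loc.occupancy(traj_n, layout, walking_mask=walking[:n])
        row = {"subject": sid, "total_distance_m": occ.total_distance_m}
        row.update({f"time_{r}_min": v for r, v in occ.room_time_min.items()})
        row.update({f"speed_{r}_mps": v for r, v in occ.room_walking_speed.items()})
        occ_rows.append(row)
        np.savetxt(sdir / "heatmap.csv", occ.heatmap, fmt="%.3f", delimiter=",")
    _write_csv(pd.DataFrame(occ_rows), run_dir / "occupancy.csv")


# ---------------------------------------------------------------------------
# stage: classify
# ---------------------------------------------------------------------------


def _windows_for_subject(cfg: RunConfig, run_dir: Path, sid: str) -> clf.LabeledWindowDataset:
    sdir = run_dir / sid
    angles = pd.read_csv(sdir / "joint_angles.csv")
    state = pd.read_csv(sdir / "truth_state.csv")
    traj = pd.read_csv(sdir / "trajectory.csv")
    n = min(len(angles), len(state), len(traj))
    acts = np.array([ACTIVITIES.index(a) for a in state["activity"][:n]])
    spec = clf.WindowSpec(cfg.window_s, rate_hz=cfg.common_hz)
    return clf.segment_windows(
        angles.iloc[:n, 1:].to_numpy(),
        acts,
        traj["room"].to_numpy(dtype=object)[:n],
        sid,
        spec,
        times=angles["time_s"].to_numpy()[:n],
    )


def stage_classify(cfg: RunConfig, run_dir: Path) -> None:
    """Windowing, features, and LOSO evaluation of the configured model."""
    parts = [_windows_for_subject(cfg, run_dir, sid) for sid in cfg.subject_ids()]
    ds = clf.LabeledWindowDataset.concatenate(parts)
    _write_csv(ds.to_frame(), run_dir / "windows.csv")

    model = (
        {"kind": "knn", "k": cfg.knn_k}
        if cfg.model == "knn"
        else {"kind": "svm", "C": cfg.svm_c, "gamma": cfg.svm_gamma}
    )
    res = clf.loso_cv(ds, model)
    res.confusion.to_frame().to_csv(run_dir / "confusion.csv")
    pred = pd.DataFrame(
        {
            "window": res.window_index,
            "subject": ds.subject[res.window_index],
            "start_s": ds.start_s[res.window_index],
            "true": np.asarray(ACTIVITIES, object)[ds.activity[res.window_index]],
            "predicted": np.asarray(ACTIVITIES, object)[res.predictions],
            "room": ds.room[res.window_index],
        }
    )
    _write_csv(pred, run_dir / "predictions.csv")
    (run_dir / "loso.json").write_text(
        json.dumps(
            {
                "mean_accuracy": res.mean_accuracy,
                "fold_subjects": res.fold_subjects,
                "fold_accuracy": res.fold_accuracy,
            },
            indent=1,
        )
    )


# ---------------------------------------------------------------------------
# stage: summarize (+ stats report)
# ---------------------------------------------------------------------------


def _episode_summaries(cfg: RunConfig, run_dir: Path):
    pred = pd.read_csv(run_dir / "predictions.csv")
    spec = clf.WindowSpec(cfg.window_s, rate_hz=cfg.common_hz)
    per_subject_pred, per_subject_meas, episode_rows = [], [], []
    for sid in cfg.subject_ids():
        sdir = run_dir / sid
        adf = pd.read_csv(sdir / "joint_angles.csv")
        angles = ori.JointAngleStream(
            times=adf["time_s"].to_numpy(),
            angles=adf.iloc[:, 1:].to_numpy(),
            rate_hz=cfg.common_hz,
            channels=tuple(adf.columns[1:]),
        )
        sub = pred[pred["subject"] == sid].sort_values("start_s")
        for source, labels in (
            ("predicted", sub["predicted"].to_numpy(dtype=object)),
            ("measured", sub["true"].to_numpy(dtype=object)),
        ):
            episodes = summ.windows_to_episodes(
                np.array([ACTIVITIES.index(a) for a in labels]),
                sub["start_s"].to_numpy(),
                spec.length_s,
                rooms=sub["room"].to_numpy(dtype=object),
                gap_tolerance_s=cfg.gap_tolerance_s,
                min_duration_s=cfg.min_duration_s,
                source=source,
            )
            # merged episodes overreach by up to half a window at each end
            trim = spec.length_s / 2.0 + summ.EPISODE_TRIM_S
            metrics = summ.episode_metrics(episodes, angles, trim_s=trim)
            if not metrics.empty:
                metrics.insert(0, "subject", sid)
                episode_rows.append(metrics)
            table = summ.activity_summary(metrics, sid)
            (per_subject_pred if source == "predicted" else per_subject_meas).append(table)
    return per_subject_pred, per_subject_meas, episode_rows


def stage_summarize(cfg: RunConfig, run_dir: Path) -> None:
    """Episodes, per-activity summaries, and predicted-vs-measured statistics."""
    pred_tables, meas_tables, episode_rows = _episode_summaries(cfg, run_dir)
    if episode_rows:
        _write_csv(pd.concat(episode_rows, ignore_index=True), run_dir / "episodes.csv")
    if pred_tables:
        _write_csv(summ.cohort_table(pred_tables), run_dir / "summary_predicted.csv")
    if meas_tables:
        _write_csv(summ.cohort_table(meas_tables), run_dir / "summary_measured.csv")
    if pred_tables and meas_tables:
        comparison = summ.compare_predicted_vs_measured(pred_tables, meas_tables)
        _write_csv(comparison, run_dir / "predicted_vs_measured.csv")


def stage_export_bvh(cfg: RunConfig, run_dir: Path, subject: str | None = None) -> Path:
    sid = subject or cfg.subject_ids()[0]
    sdir = run_dir / sid
    adf = pd.read_csv(sdir / "joint_angles.csv")
    tdf = pd.read_csv(sdir / "trajectory.csv")
    n = min(len(adf), len(tdf))
    angles = ori.JointAngleStream(
        times=adf["time_s"].to_numpy()[:n],
        angles=adf.iloc[:n, 1:].to_numpy(),
        rate_hz=cfg.common_hz,
        channels=tuple(adf.columns[1:]),
    )
    return export_pose_stream(
        angles,
        tdf[["x_m", "y_m"]].to_numpy()[:n],
        sdir / "avatar.bvh",
        json_path=sdir / "pose_stream.json",
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "calibrate": stage_calibrate,
    "angles": stage_angles,
    "localize": stage_localize,
    "classify": stage_classify,
    "summarize": stage_summarize,
}


def run_pipeline(cfg: RunConfig, run_dir: str | Path) -> dict:
    """Run all stages in order; write a manifest; return it."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    completed = []
    for name in STAGES:
        try:
            _STAGE_FUNCS[name](cfg, run_dir)
        except Exception as exc:
            manifest = {
                "config": cfg.to_dict(),
                "stages_completed": completed,
                "failed_stage": name,
                "error": str(exc),
            }
            (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        completed.append(name)
        log.info("stage %s complete", name)
    manifest = {"config": cfg.to_dict(), "stages_completed": completed}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
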