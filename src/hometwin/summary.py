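"""Episode-level mobility outcomes.

Window-level activity labels (predicted or ground truth) are merged into
contiguous activity episodes, from which a study's per-activity outcomes are
computed: occurrence counts, accumulated durations, and per-episode maxima of
the clinically reported range-of-motion channels (shoulder plane of
elevation and elevation, hip flexion, knee flexion, ankle dorsiflexion and
plantarflexion — the last two being the positive and negative extrema of one
signed channel).

Aggregation averages episodes within subject first, then reports mean +- SD
across subjects, matching per-subject paired testing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orientation import JointAngleStream
from .taxonomy import ACTIVITIES

#: ROM outcome -> (channel, sign); plantarflexion is the negated minimum of
#: the signed dorsi/plantar channel
ROM_OUTCOMES: dict[str, tuple[str, float]] = {
    "max_shoulder_plane_of_elevation": ("shoulder_r.plane_of_elevation", +1.0),
    "max_shoulder_elevation": ("shoulder_r.elevation", +1.0),
    "max_hip_flexion": ("hip_r.flexion", +1.0),
    "max_knee_flexion": ("knee_r.flexion", +1.0),
    "max_ankle_dorsiflexion": ("ankle_r.dorsi_plantar", +1.0),
    "max_ankle_plantarflexion": ("ankle_r.dorsi_plantar", -1.0),
}

DEFAULT_MIN_DURATION_S = 0.5
#: margin trimmed from each episode end before taking extrema, so blended
#: boundary samples belonging to the neighboring activity are excluded
EPISODE_TRIM_S = 0.2


@dataclass
class ActivityEpisode:
    activity: str
    start: float
    end: float
    room: str
    source: str = "predicted"   # "measured" | "predicted"

    @property
    def duration(self) -> float:
        return self.end - self.start


def windows_to_episodes(
    labels: np.ndarray,
    start_times: np.ndarray,
    window_length_s: float,
    rooms: np.ndarray | None = None,
    gap_tolerance_s: float = 0.0,
    min_duration_s: float = 0.0,
    source: str = "predicted",
) -> list[ActivityEpisode]:
    """Merge time-ordered window labels into episodes.

    Consecutive equal labels merge; a different-label gap no longer than
    ``gap_tolerance_s`` between two runs of one label is bridged; episodes
    shorter than ``min_duration_s`` are discarded.
    """
    labels = np.asarray(labels)
    start_times = np.asarray(start_times, float)
    if labels.size == 0:
        return []
    if np.any(np.diff(start_times) < 0):
        raise ValueError("windows must be time-ordered")
    rooms = rooms if rooms is not None else np.full(labels.size, "none", dtype=object)

    runs: list[tuple[object, float, float, list]] = []  # label, start, end, rooms
    for i in range(labels.size):
        t0, t1 = start_times[i], start_times[i] + window_length_s
        if runs and runs[-1][0] == labels[i] and t0 <= runs[-1][2] + 1e-9:
            runs[-1] = (labels[i], runs[-1][1], t1, runs[-1][3] + [rooms[i]])
        else:
            runs.append((labels[i], t0, t1, [rooms[i]]))

    merged: list[tuple[object, float, float, list]] = []
    for run in runs:
        if (
            merged
            and merged[-1][0] == run[0]
            and (gap_tolerance_s > 0 or run[1] <= merged[-1][2] + 1e-9)
            and run[1] - merged[-1][2] <= gap_tolerance_s + 1e-9
        ):
            merged[-1] = (run[0], merged[-1][1], run[2], merged[-1][3] + run[3])
        elif (
            gap_tolerance_s > 0
            and len(merged) >= 2
            and merged[-2][0] == run[0]
            and run[1] - merged[-2][2] <= gap_tolerance_s + 1e-9
        ):
            # a single short mislabeled run inside a longer one: bridge over it
            merged.pop()
            merged[-1] = (run[0], merged[-1][1], run[2], merged[-1][3] + run[3])
        else:
            merged.append(run)

    episodes = []
    for label, t0, t1, rms in merged:
        if t1 - t0 < min_duration_s - 1e-9:
            continue
        vals, counts = np.unique(np.asarray(rms, dtype=object), return_counts=True)
        room = str(vals[np.argmax(counts)])
        name = ACTIVITIES[int(label)] if not isinstance(label, str) else label
        episodes.append(ActivityEpisode(name, float(t0), float(t1), room, source))
    return episodes


def episode_metrics(
    episodes: list[ActivityEpisode],
    angles: JointAngleStream,
    trim_s: float = EPISODE_TRIM_S,
) -> pd.DataFrame:
    """Per-episode ROM extrema: one row per episode, one column per outcome."""
    rows = []
    t0, t1 = angles.times[0], angles.times[-1]
    for ep in episodes:
        if ep.start < t0 - 1e-9 or ep.end > t1 + 1.0 / angles.rate_hz + 1e-9:
            warnings.warn(
                f"episode {ep.activity} [{ep.start:.2f}, {ep.end:.2f}] outside "
                "angle stream span; skipped"
            )
            continue
        lo, hi = ep.start + trim_s, ep.end - trim_s
        if hi <= lo:  # too short to trim; use the full span
            lo, hi = ep.start, ep.end
        sel = (angles.times >= lo - 1e-9) & (angles.times < hi + 1e-9)
        if not sel.any():
            continue
        row = {
            "activity": ep.activity,
            "room": ep.room,
            "start_s": ep.start,
            "end_s": ep.end,
            "duration_s": ep.duration,
            "source": ep.source,
        }
        for outcome, (channel, sign) in ROM_OUTCOMES.items():
            row[outcome] = float(np.max(sign * angles.channel(channel)[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


def activity_summary(metrics: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    """Per-activity within-subject summary: count, accumulated duration, mean
    of per-episode ROM maxima."""
    if metrics.empty:
        return pd.DataFrame()
    g = metrics.groupby("activity")
    out = g.agg(
        n_occurrences=("activity", "size"),
        accumulated_duration_s=("duration_s", "sum"),
        **{k: (k, "mean") for k in ROM_OUTCOMES},
    ).reset_index()
    out.insert(0, "subject", subject_id)
    return out


def cohort_table(per_subject: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean +- SD per activity for each outcome."""
    df = pd.concat(per_subject, ignore_index=True)
    cols = ["n_occurrences", "accumulated_duration_s", *ROM_OUTCOMES]
    agg = df.groupby("activity")[cols].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    return agg.reset_index()


def compare_predicted_vs_measured(
    pred: list[pd.DataFrame],
    meas: list[pd.DataFrame],
    outcomes: list[str] | None = None,
) -> pd.DataFrame:
    """Paired per-subject comparison of predicted vs measured summaries.

    One row per (activity, outcome): measured and predicted cohort mean +- SD,
    per-subject paired differences forwarded to the statistics layer.
    Activities present in only one arm are flagged, not dropped.
    """
    from .stats import bh_fdr, paired_t

    outcomes = outcomes or ["n_occurrences", "accumulated_duration_s", *ROM_OUTCOMES]
    p = pd.concat(pred, ignore_index=True)
    m = pd.concat(meas, ignore_index=True)
    rows = []
    activities = sorted(set(p["activity"]) | set(m["activity"]))
    for outcome in outcomes:
        for act in activities:
            pm = p[p["activity"] == act].set_index("subject")[outcome]
            mm = m[m["activity"] == act].set_index("subject")[outcome]
            common = sorted(set(pm.index) & set(mm.index))
            row = {
                "outcome": outcome,
                "activity": act,
                "n_pairs": len(common),
                "flag": "" if len(common) >= 2 else "insufficient-pairs",
                "measured_mean": float(mm.mean()) if len(mm) else np.nan,
                "measured_sd": float(mm.std(ddof=1)) if len(mm) > 1 else np.nan,
                "predicted_mean": float(pm.mean()) if len(pm) else np.nan,
                "predicted_sd": float(pm.std(ddof=1)) if len(pm) > 1 else np.nan,
            }
            if len(common) >= 2:
                res = paired_t(pm[common].to_numpy(), mm[common].to_numpy())
                row.update(
                    mean_difference=res.mean_difference,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    t=res.t,
                    p_raw=res.p,
                    cohens_d=res.cohens_d,
                    degenerate=res.degenerate,
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    # FDR within each outcome family (one family per comparison table)
    table["p_fdr"] = np.nan
    if "p_raw" in table.columns:
        for outcome in outcomes:
            sel = (table["outcome"] == outcome) & table["p_raw"].notna()
            if sel.any():
                table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p_raw"].to_numpy())
    return table
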