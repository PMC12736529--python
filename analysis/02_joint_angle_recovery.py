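#!/usr/bin/env python
"""Validate joint-angle recovery through the sensing chain.

One subject's 5-minute recording is pushed through sensor simulation with
arbitrary mounting rotations, two-pose TRIAD calibration, slerp resampling
and Euler decomposition; recovered channels are compared with ground truth at
0 and 1 degree orientation noise, and after re-drawing the mounting
rotations (calibration invariance). Writes a per-channel RMSE table.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hometwin.cohort import angle_rmse_by_channel, build_subject
from hometwin.config import RunConfig
from hometwin.synth import generate_layout
from hometwin.taxonomy import CHANNELS

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cfg = RunConfig(root_seed=args.seed, n_subjects=1, duration_s=300.0, imu_noise_deg=0.0)
layout = generate_layout(cfg.root_seed)
s = args.seed

clean = build_subject(layout, cfg, "s01", s, s, s)
noisy = build_subject(layout, cfg, "s01", s, s, s + 1, noise_deg=1.0)
remount = build_subject(layout, cfg, "s01", s, s, s, mounting_seed=s + 2)

rmse0 = angle_rmse_by_channel(clean)
rmse1 = angle_rmse_by_channel(noisy)
n = min(clean.n_common, remount.n_common)
diff = (clean.angles.angles[:n] - remount.angles.angles[:n] + 180) % 360 - 180
rmse_mount = np.sqrt((diff**2).mean(axis=0))

table = pd.DataFrame(
    {
        "channel": CHANNELS,
        "rmse_noiseless_deg": rmse0.round(4),
        "rmse_1deg_noise_deg": rmse1.round(4),
        "rmse_mounting_redraw_deg": rmse_mount.round(6),
    }
)
table.to_csv(args.out / "angle_recovery_rmse.csv", index=False)

print(f"worst-channel RMSE, noiseless sensing:   {rmse0.max():.4f} deg")
print(f"worst-channel RMSE, 1 deg sensor noise:  {rmse1.max():.4f} deg")
print(f"worst-channel change after re-mounting:  {rmse_mount.max():.6f} deg")
print("the two-pose calibration absorbs arbitrary mounting; smoothing keeps the")
print("noisy proper-Euler channels (plane of elevation/inclination) bounded.")
print(f"table: {args.out}/angle_recovery_rmse.csv")
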