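"""Run configuration: rates, noise levels, model and merge parameters.

Defaults mirror the study protocol: 12 sensors at 225 Hz fused-orientation
output, UWB ranging at ~5 Hz, everything resampled to a common 100 Hz grid,
50%-overlap windows on a 0.1-2.0 s grid with KNN (9 neighbors, 1.3 s window)
as the selected classifier, and a 10-subject cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    root_seed: int = 1
    n_subjects: int = 10
    duration_s: float = 600.0

    imu_hz: float = 225.0
    uwb_hz: float = 5.0
    common_hz: float = 100.0

    imu_noise_deg: float = 0.3
    imu_drift_deg_per_min: float = 0.0
    pose_noise_deg: float = 0.0
    uwb_noise_m: float = 0.12

    angle_lowpass_hz: float = 8.0
    position_lowpass_hz: float = 0.5

    window_s: float = 1.3
    model: str = "knn"          # "knn" | "svm"
    knn_k: int = 9
    svm_c: float = 10.0
    svm_gamma: float | str = "scale"

    gap_tolerance_s: float = 0.65   # one window step at the default window
    min_duration_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("imu_hz", "uwb_hz", "common_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1 or self.duration_s <= 0:
            raise ValueError("need at least one subject and a positive duration")

    # -- seed derivation: one root seed, named substreams per stage ---------
    def subject_seeds(self, stage: str) -> list[int]:
        import numpy as np

        tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
        ss = np.random.SeedSequence([int(self.root_seed), tag])
        return [int(s) for s in ss.generate_state(self.n_subjects) % (2**31)]

    def subject_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_subjects)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=True)
            if path.suffix in (".yml", ".yaml")
            else json.dumps(self.to_dict(), indent=1, sort_keys=True)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        obj = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yml", ".yaml")
            else json.loads(path.read_text())
        )
        return cls(**obj)
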