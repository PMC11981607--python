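"""Run configuration: every detector threshold in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _default_params() -> dict:
    # every tunable appearing in any detector, with the package defaults
    return {
        "photometry": {
            "polyfit_degree": 2,
            "baseline_duration_s": None,  # drawn uniformly from [5, 10] s
            "robust_baseline": True,
            "threshold_multiplier": 3.0,
            "merge_gap_s": 0.1,
            "min_duration_samples": 5,
        },
        "behavior": {
            "smooth_window_s": 0.2,
            "min_dwell_frames": 3,
            "run_threshold_mm_s": 400.0,
            "fast_run_min_dur_s": 0.25,
            "fast_run_merge_gap_s": 0.2,
            "pause_speed_mm_s": 20.0,
            "pause_min_s": 0.5,
        },
        "startle": {
            "response_window_s": 0.2,
            "pre_window_s": 0.1,
            "move_threshold": 50.0,
            "amplitude_method": "peak",
        },
        "ephys": {
            "spike_height_mv": 0.0,
            "spike_min_separation_s": 0.001,
            "ap_slope_criterion_v_per_s": 20.0,
            "mini_threshold_pa": 5.0,
            "mini_min_interval_s": 0.005,
            "ltp_baseline_min": 10.0,
        },
    }


@dataclass
class RunConfig:
    """Stage parameters, seed, paths and group labels for one pipeline run."""

    seed: int = 0
    input_path: str = ""
    output_dir: str = "results"
    group_labels: tuple = ("control", "acute_heat", "chronic_heat")
    params: dict = field(default_factory=_default_params)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["group_labels"] = tuple(raw.get("group_labels", ()))
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the full configuration for run manifests."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
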