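"""Study configuration: every tunable threshold of the pipeline in one
versioned, serializable schema.

Defaults reproduce the laboratory protocol the pipeline models: 1 kHz
force / 2 kHz EMG sampling, 4th-order zero-phase Butterworth filters
(150 Hz low-pass for force, 6-450 Hz band-pass for EMG), baseline
slope rejection above 1.5 signal-units/s, peak rejection below 75%
MVF, take-off below 5 N, incremental loads {17, 30, 45, 60, 75} kg,
prescription loads {20, 40, 60} kg at a target mean propulsive
velocity of 1 m/s, and a 15-repetition repeated-jump test.
"""

from __future__ import annotations

import hashlib
import json
from typing import Tuple

import yaml
from pydantic import BaseModel, field_validator

__all__ = ["StudyConfig"]


class StudyConfig(BaseModel):
    schema_version: int = 1
    seed: int = 1

    # signal acquisition / filtering
    force_fs_hz: float = 1000.0
    emg_fs_hz: float = 2000.0
    lowpass_cutoff_hz: float = 150.0
    filter_order: int = 4
    emg_band_hz: Tuple[float, float] = (6.0, 450.0)

    # onset detection and screening
    trigger_sd_mult: float = 8.0
    baseline_window_ms: float = 200.0
    slope_window_ms: float = 100.0
    slope_limit: float = 1.5          # signal-units per second
    peak_fraction: float = 0.75       # of session MVF
    emg_k_sd: float = 3.0
    emg_sustain_ms: float = 10.0
    emg_baseline_ms: float = 100.0

    # jump analysis
    takeoff_threshold_n: float = 5.0
    quiet_window_s: Tuple[float, float] = (0.0, 0.4)
    displacement_bounds_m: Tuple[float, float] = (0.15, 0.60)
    incremental_loads_kg: Tuple[float, ...] = (17.0, 30.0, 45.0, 60.0, 75.0)
    prescription_loads_kg: Tuple[float, ...] = (20.0, 40.0, 60.0)
    target_velocity_ms: float = 1.0
    n_cmj15: int = 15

    # statistics
    icc_form: str = "ICC2"
    cv_mode: str = "typical_error"
    d_ci_method: str = "nct"
    swc: float = 0.2

    # synthetic study layout
    n_per_group: int = 12
    n_explosive_trials: int = 10
    n_mvc_trials: int = 3

    @field_validator("icc_form")
    @classmethod
    def _icc(cls, v):
        if v not in ("ICC2", "ICC3"):
            raise ValueError("icc_form must be ICC2 or ICC3")
        return v

    @field_validator("cv_mode")
    @classmethod
    def _cv(cls, v):
        if v not in ("typical_error", "per_subject"):
            raise ValueError("cv_mode must be typical_error or per_subject")
        return v

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable digest of the full configuration (recorded in run logs)."""
        canon = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
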