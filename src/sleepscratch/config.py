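"""Pipeline configuration.

Every constant of the method is a configuration default rather than a
hard-coded value: 20 Hz analysis rate, 6-h day validity, 25 degC wear rule,
0.1-degree TSO threshold floor, 1-min sleep epochs with the Cole-Kripke
weighted sum and Webster rescoring, 3-s scratch windows gated at a rolling
CoV of 0.023, a 0.25 Hz first-order high-pass, 50 forest trees and a 0.5
prediction threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .sleepwake import COLE_KRIPKE_WEIGHTS, DEFAULT_SCALE


@dataclass
class PipelineConfig:
    # preprocessing
    target_rate: float = 20.0
    min_day_hours: float = 6.0
    # wear + TSO
    wear_threshold: float = 25.0
    tso_threshold_floor: float = 0.1
    tso_percentile: float = 25.0
    tso_min_block_min: float = 30.0
    tso_merge_gap_min: float = 30.0
    # sleep/wake
    epoch_s: int = 60
    ck_weights: tuple = COLE_KRIPKE_WEIGHTS
    ck_scale: float = DEFAULT_SCALE
    activity_noise_var: float = 0.0
    webster_rules: tuple = (True, True, True, True, True)
    # scratch
    window_s: float = 3.0
    train_overlap: float = 0.5
    cov_threshold: float = 0.023
    cov_subwindow_s: float = 0.5
    hp_cutoff_hz: float = 0.25
    hp_order: int = 1
    n_estimators: int = 50
    predict_threshold: float = 0.5
    rfecv_cv: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("ck_weights", "webster_rules"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ck_weights"] = list(data["ck_weights"])
        data["webster_rules"] = list(data["webster_rules"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if len(self.ck_weights) != 7:
            raise ValueError("ck_weights must have 7 entries (epochs t-4..t+2)")
        if len(self.webster_rules) != 5:
            raise ValueError("webster_rules must have 5 on/off entries")
        if not 0 <= self.train_overlap < 1:
            raise ValueError("train_overlap must be in [0, 1)")
        if self.window_s <= 0 or self.epoch_s <= 0:
            raise ValueError("window and epoch lengths must be positive")
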