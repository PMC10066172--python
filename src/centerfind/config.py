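"""Pipeline configuration: one YAML-serializable block of every threshold.

Defaults are the analysis constants used throughout: 5 s stay criterion,
3 s approach window, 95% on-spot exclusion, 0.5 cm/s rest speed, 2 cm
wall band, symmetric2 DTW, k = 4 with a 2..8 scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .arena import SHAPE_SPECS

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    shape: str = "circle"
    stay_min_s: float = 5.0
    stay_max_gap_s: float = 0.2
    approach_window_s: float = 3.0
    max_on_spot_frac: float = 0.95
    rest_speed_cms: float = 0.5
    wall_band_cm: float = 2.0
    occupancy_bin_cm: float = 1.0
    dtw_step_pattern: str = "symmetric2"
    dtw_window: int | None = None
    dtw_normalize: str = "none"
    k: int = 4
    k_scan: list = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    log_latency_offset_s: float = 1.0
    n_bootstrap: int = 2000
    seed: int = 0
    trial_s: float = 300.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_SPECS:
            raise ConfigError(
                f"unknown shape {self.shape!r}; valid options: {sorted(SHAPE_SPECS)}"
            )
        for name in ("stay_min_s", "approach_window_s", "rest_speed_cms",
                     "wall_band_cm", "occupancy_bin_cm", "trial_s", "fps"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.k not in self.k_scan:
            raise ConfigError("k_scan must contain k")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
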