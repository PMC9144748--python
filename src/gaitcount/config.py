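"""Pipeline configuration with the study's protocol constants as defaults.

Every default mirrors the acquisition/processing protocol: 30 Hz
sampling, 2 s windows with 50 % overlap, a 30 N detection threshold with
a 0.2 s refractory period, a 0.5-60 N sensor range, a 5-tap moving
average (half-width 2), and a 7:3 train/test split.  Configurations
round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    sample_rate_hz: float = 30.0
    window_s: float = 2.0
    overlap_frac: float = 0.5
    threshold_n: float = 30.0
    min_interval_s: float = 0.2
    clip_low_n: float = 0.5
    clip_high_n: float = 60.0
    maf_half_width: int = 2
    train_frac: float = 0.7
    split_mode: str = "chronological"
    seed: int = 0
    classifier_algorithm: str = "random_forest"
    regressor_algorithms: list = field(
        default_factory=lambda: ["random_forest", "svm", "mlp", "ensemble"]
    )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
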