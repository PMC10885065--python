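"""Run configuration shared by the CLI commands."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError
from .ipaq import METWeights


@dataclass
class RunConfig:
    """Tunables a CLI invocation may override via ``--config config.yaml``."""

    met_weights: METWeights = field(default_factory=METWeights)
    stage_duration_s: float = 60.0
    target_fraction: float = 0.8
    alpha: float = 0.05
    d_variant: str = "pooled_sd"
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if not 0 < self.target_fraction <= 1:
            raise ValidationError("target_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "met_weights" in raw:
            raw["met_weights"] = METWeights(**raw["met_weights"])
        return cls(**raw)
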