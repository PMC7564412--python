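"""Declarative run configuration.

Every numeric constant a run depends on — nuclide constants file, organ ->
model map, injected activity, rounding, seeds, normal ranges, censor day —
lives here and is echoed into the run manifest, so a dose table can always
be traced back to the exact constants that produced it.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigError

__all__ = ["NormalRange", "RunConfig", "load_config"]


class NormalRange(BaseModel):
    lower: float = 0.0
    upper: float
    units: str = ""
    citation: str = ""

    @field_validator("upper")
    @classmethod
    def _ordered(cls, v: float, info) -> float:
        if "lower" in info.data and v < info.data["lower"]:
            raise ValueError("upper limit below lower limit")
        return v

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower, self.upper)


class RunConfig(BaseModel):
    nuclide_file: Path | None = None
    organ_model_file: Path | None = None
    injected_activity_kbq: float = Field(740.0, ge=0)
    rounding_decimals: int = 1
    seed: int = Field(12345, ge=0)
    censor_day: float = Field(160.0, gt=0)
    rbe: float = Field(4.0, gt=0)
    undetermined_is_event: bool = True
    normal_ranges: dict[str, NormalRange] = Field(default_factory=dict)

    @property
    def injected_activity_mbq(self) -> float:
        return self.injected_activity_kbq / 1000.0

    def range_limits(self) -> dict[str, tuple[float, float]]:
        return {k: v.as_tuple() for k, v in self.normal_ranges.items()}

    def check_files(self) -> None:
        for p in (self.nuclide_file, self.organ_model_file):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured file does not exist: {p}")

    def manifest_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run config; defaults to the shipped configuration."""
    if path is None:
        text = resources.files("atdosim.data").joinpath("default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    cfg = RunConfig.model_validate(raw)
    cfg.check_files()
    return cfg
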