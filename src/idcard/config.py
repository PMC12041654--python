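"""Run configuration: defaults, YAML loading, CLI overrides.

All analysis parameters live in one ``RunConfig`` with the defaults used
throughout: ΔRt = Δm/z = 0.05, Rt window 1.00–26.00 min, 100-ion cards,
a 50% adulteration threshold and pair-count MC numerators.  A YAML config
file may override any field, and CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .feature_model import ToleranceSpec

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    delta_rt: float = 0.05
    delta_mz: float = 0.05
    rt_min: float = 1.00
    rt_max: float = 26.00
    top_n: int = 100
    strategy: str = "shared_vs_shared"
    threshold: float = 50.0
    numerator_mode: str = "pairs"
    blank_first: bool = True
    quorum: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("shared_vs_shared", "shared_vs_raw"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.numerator_mode not in ("pairs", "unique"):
            raise ConfigurationError(f"unknown numerator_mode {self.numerator_mode!r}")
        if self.delta_rt < 0 or self.delta_mz < 0:
            raise ConfigurationError("tolerances must be nonnegative")
        if not self.rt_min < self.rt_max:
            raise ConfigurationError("rt_min must be below rt_max")
        if self.top_n < 1:
            raise ConfigurationError("top_n must be >= 1")

    @property
    def tolerance(self) -> ToleranceSpec:
        return ToleranceSpec(self.delta_rt, self.delta_mz)

    @property
    def rt_window(self) -> tuple[float, float]:
        return (self.rt_min, self.rt_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def override(self, **kwargs) -> "RunConfig":
        """New config with the non-None keyword values applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
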