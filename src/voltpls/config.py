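"""Run configuration: schema-validated YAML with simulator, filter and PLS
sections.  Unknown keys are rejected; the seed is mandatory (it drives every
stochastic step of a run)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .processing import FilterSpec
from .simulate import ConditionSet, GridSpec, NoiseModel

__all__ = ["ConfigError", "DesignConfig", "PLSConfig", "RunConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class PLSConfig:
    max_lv: int = 8
    n_lv: int | None = None   # override automatic LV selection

    def __post_init__(self) -> None:
        if self.max_lv < 1:
            raise ConfigError("pls.max_lv must be >= 1")
        if self.n_lv is not None and self.n_lv < 1:
            raise ConfigError("pls.n_lv must be >= 1")


@dataclass(frozen=True)
class DesignConfig:
    n_train: int = 17
    n_test: int = 12
    method: str = "uniform"

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ConfigError("design sizes must be >= 1")
        if self.method not in ("uniform", "lhs"):
            raise ConfigError("design.method must be 'uniform' or 'lhs'")


_SECTIONS = {
    "conditions": ConditionSet,
    "noise": NoiseModel,
    "grid": GridSpec,
    "filter": FilterSpec,
    "pls": PLSConfig,
    "design": DesignConfig,
}


def _build_section(cls, data: dict, name: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except ValueError as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs, reproducibly."""

    seed: int
    profile: str = "modified"
    conditions: ConditionSet = field(default_factory=ConditionSet)
    noise: NoiseModel = field(default_factory=NoiseModel)
    grid: GridSpec = field(default_factory=GridSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    pls: PLSConfig = field(default_factory=PLSConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    report_decimals: int = 2

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("a seed is mandatory")
        kwargs = {}
        for key, value in data.items():
            if key in _SECTIONS:
                kwargs[key] = _build_section(_SECTIONS[key], value, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "profile": self.profile,
               "report_decimals": self.report_decimals}
        for name, cls in _SECTIONS.items():
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
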