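"""Run configuration: one YAML file covering every stage, unknown keys rejected."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .analytics import BreakConfig
from .engine import EngineConfig
from .errors import ConfigError
from .features import MfccConfig
from .sim import SimConfig


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    k: int = 3
    recheck_min: float = 15.0
    n_trim: int = 2
    sim: SimConfig = field(default_factory=SimConfig)
    mfcc: MfccConfig = field(default_factory=MfccConfig)
    breaks: BreakConfig = field(default_factory=BreakConfig)

    def engine_config(self) -> EngineConfig:
        return EngineConfig(recheck_min=self.recheck_min, k=self.k, mfcc=self.mfcc)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "k": self.k,
            "recheck_min": self.recheck_min,
            "n_trim": self.n_trim,
            "sim": asdict(self.sim),
            "mfcc": asdict(self.mfcc),
            "breaks": asdict(self.breaks),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        sections = {
            "sim": _build(SimConfig, data.pop("sim", {}), "sim"),
            "mfcc": _build(MfccConfig, data.pop("mfcc", {}), "mfcc"),
            "breaks": _build(BreakConfig, data.pop("breaks", {}), "breaks"),
        }
        top_known = {"seed", "k", "recheck_min", "n_trim"}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**data, **sections)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
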