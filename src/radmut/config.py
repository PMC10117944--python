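"""Run configuration: YAML-backed, schema-validated, fully serializable.

A run is reproducible from config + seed alone.  Unknown keys are
rejected with a :class:`ConfigError` listing the offending names; all
thresholds default to the published filter/classification values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError
from .pipeline import ClassifyOptions
from .site_filtering import FilterConfig

__all__ = ["RunConfig", "load_config"]


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown config keys under {path!r}: {sorted(unknown)}"
        )
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid config under {path!r}: {exc}") from exc


@dataclass(frozen=True)
class GenomeConfig:
    length: int = 600_000
    gc: float = 0.36
    n_chroms: int = 3


@dataclass(frozen=True)
class GenesConfig:
    n: int = 150
    mean_length: int = 1500


@dataclass(frozen=True)
class SimulateConfig:
    profiles: tuple = (
        "gamma_dry",
        "gamma_seedling",
        "carbon_dry",
        "carbon_seedling",
    )
    n_plants: int = 12
    events_per_plant: float = 25.0
    del_large_max: int = 20_000


@dataclass(frozen=True)
class NoiseConfig:
    depth: int = 40
    af_binomial: bool = False
    fp_shared_rate: float = 0.0


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    correction: str = "holm"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class SurvivalConfig:
    # Relative doses are multiples of each treatment's true Dq.
    doses_rel: tuple = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
    n_per_replicate: int = 30
    replicates: int = 3
    curves: dict = field(
        default_factory=lambda: {
            "gamma_dry": {"d0": 1861.6, "m": 3.0},
            "gamma_seedling": {"d0": 141.1, "m": 3.0},
            "carbon_dry": {"d0": 219.4, "m": 3.0},
            "carbon_seedling": {"d0": 37.3, "m": 3.0},
        }
    )


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GenesConfig = field(default_factory=GenesConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    classify: ClassifyOptions = field(default_factory=ClassifyOptions)
    stats: StatsConfig = field(default_factory=StatsConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "genome": GenomeConfig,
            "genes": GenesConfig,
            "simulate": SimulateConfig,
            "noise": NoiseConfig,
            "filter": FilterConfig,
            "classify": ClassifyOptions,
            "stats": StatsConfig,
            "survival": SurvivalConfig,
        }
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict = {"seed": int(data.get("seed", 1))}
        for name, section_cls in sections.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            if name in ("simulate", "survival"):
                for key in ("profiles", "doses_rel"):
                    if key in section and isinstance(section[key], list):
                        section = {**section, key: tuple(section[key])}
            kwargs[name] = _build(section_cls, section, name)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return RunConfig.from_dict(data)
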