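"""Structured configuration for simulations and experiments.

Every default in the package is overridable from a YAML file. The defaults
describe the packaged desk-scale study system: a 21 x 21 grid of 8-km cells
(a 168 x 168 km arena) with one community of 25 wood-hauling households at
the centre, a baseline demand of seven truckloads per household per year,
and a 120 km maximum one-way trip radius.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .demography import DemographyParams, SpeciesParams
from .errors import ConfigError
from .forcing import DEFAULT_TARGETS, SUPPLY_SCENARIOS
from .harvest import HarvestParams
from .landscape import SPECIES, GridSpec


@dataclass(frozen=True)
class LandscapeConfig:
    """Suitability and initial-stocking choices."""

    correlation_length_km: float = 24.0
    dead_fraction: float = 0.10
    age_init: str = "stationary"  # or "exponential"
    age_init_mean: float = 80.0
    #: per-species initial stems per cell at suitability 1; ``None`` means
    #: the demographic stationary density (start near equilibrium)
    density: dict | None = None
    max_per_cell: int | None = None


@dataclass(frozen=True)
class CalendarConfig:
    start_year: int = 2020
    horizon_year: int = 2100
    spin_up_years: int = 30

    def __post_init__(self) -> None:
        if self.horizon_year <= self.start_year:
            raise ConfigError("horizon_year must exceed start_year")
        if self.spin_up_years < 0:
            raise ConfigError("spin_up_years must be >= 0")

    @property
    def years(self) -> range:
        return range(self.start_year, self.horizon_year + 1)


@dataclass(frozen=True)
class ForcingConfig:
    targets: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    rel_tol: float = 1e-3

    def __post_init__(self) -> None:
        for sc, t in self.targets.items():
            if sc not in SUPPLY_SCENARIOS:
                raise ConfigError(f"unknown supply scenario {sc!r} in targets")
            if not (0.0 <= t <= 1.0):
                raise ConfigError(
                    f"target reduction for {sc!r} must lie in [0, 1], got {t}"
                )


@dataclass(frozen=True)
class LevelsConfig:
    """Factor-level encodings for the 3 x 3 x 3 experiment."""

    iek: dict = field(
        default_factory=lambda: {"full": 1.0, "partial": 0.5, "none": 0.0}
    )
    demand: dict = field(
        default_factory=lambda: {"low": 0.5, "current": 1.0, "high": 1.5}
    )
    baseline_demand_loads: float = 7.0

    def __post_init__(self) -> None:
        for name, a in self.iek.items():
            if not (0.0 <= a <= 1.0):
                raise ConfigError(
                    f"IEK adherence for {name!r} must lie in [0, 1], got {a}"
                )
        for name, m in self.demand.items():
            if m < 0:
                raise ConfigError(
                    f"demand multiplier for {name!r} must be >= 0, got {m}"
                )
        if self.baseline_demand_loads < 0:
            raise ConfigError("baseline_demand_loads must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            nx=21, ny=21, cell_km=8.0, central_places=((10, 10),)
        )
    )
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    demography: DemographyParams = field(default_factory=DemographyParams)
    calendar: CalendarConfig = field(default_factory=CalendarConfig)
    forcing: ForcingConfig = field(default_factory=ForcingConfig)
    harvest: HarvestParams = field(default_factory=HarvestParams)
    levels: LevelsConfig = field(default_factory=LevelsConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"]["central_places"] = [
            list(cp) for cp in self.grid.central_places
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        kwargs = {}
        if "grid" in d:
            g = dict(d["grid"])
            if "central_places" in g:
                g["central_places"] = tuple(tuple(cp) for cp in g["central_places"])
            kwargs["grid"] = GridSpec(**g)
        if "landscape" in d:
            kwargs["landscape"] = LandscapeConfig(**d["landscape"])
        if "demography" in d:
            dm = d["demography"]
            kwargs["demography"] = DemographyParams(
                **{sp: SpeciesParams(**dm[sp]) for sp in SPECIES if sp in dm}
            )
        if "calendar" in d:
            kwargs["calendar"] = CalendarConfig(**d["calendar"])
        if "forcing" in d:
            kwargs["forcing"] = ForcingConfig(**d["forcing"])
        if "harvest" in d:
            kwargs["harvest"] = HarvestParams(**d["harvest"])
        if "levels" in d:
            kwargs["levels"] = LevelsConfig(**d["levels"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable digest of the full configuration, for run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config() -> SimulationConfig:
    return SimulationConfig()


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(d)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
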