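"""Run configuration: one YAML document drives the whole pipeline.

The document has one section per stage (seascape, currents, climate,
dispersal, events, curves, surveys, reach); unknown keys raise a schema
error with the offending field path, and every section falls back to the
stage defaults when omitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

from reefsources.connectivity import DEFAULT_MORTALITY, DEFAULT_SHAPES
from reefsources.dispersal import DispersalParams
from reefsources.synth.climate import ClimateConfig
from reefsources.synth.currents import CurrentsConfig
from reefsources.synth.seascape import ConfigError, PlantedConfig, SeascapeConfig
from reefsources.synth.surveys import SurveyConfig

__all__ = ["EventConfig", "CurveConfig", "ReachConfig", "RunConfig",
           "load_config", "default_demo_config"]


@dataclass(frozen=True)
class EventConfig:
    """Spawning-event schedule: n_events releases spaced along the record."""

    n_events: int = 16
    spacing_days: float = 5.0
    start_hours: float = 0.0

    def release_times(self) -> list[float]:
        return [self.start_hours + i * self.spacing_days * 24.0
                for i in range(self.n_events)]


@dataclass(frozen=True)
class CurveConfig:
    shapes: tuple[float, ...] = DEFAULT_SHAPES
    mortality: float = DEFAULT_MORTALITY


@dataclass(frozen=True)
class ReachConfig:
    durations_days: tuple[float, ...] = (1, 2, 5, 10, 15, 20, 25, 30)
    steps: tuple[int, ...] = (1, 2, 3, 5, 10)


@dataclass(frozen=True)
class RunConfig:
    seascape: SeascapeConfig = field(default_factory=SeascapeConfig)
    currents: CurrentsConfig = field(default_factory=CurrentsConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    dispersal: DispersalParams = field(default_factory=DispersalParams)
    events: EventConfig = field(default_factory=EventConfig)
    curves: CurveConfig = field(default_factory=CurveConfig)
    surveys: SurveyConfig = field(default_factory=SurveyConfig)
    reach: ReachConfig = field(default_factory=ReachConfig)
    #: number of planted warming-event years in the synthetic climate
    n_thermal_events: int = 10

    def validate(self) -> None:
        self.seascape.validate()
        span_needed = (self.events.release_times()[-1]
                       + self.dispersal.max_days * 24.0)
        self.currents.validate(min_span_hours=span_needed)
        self.climate.validate()


_SECTION_TYPES: dict[str, type] = {
    "seascape": SeascapeConfig,
    "currents": CurrentsConfig,
    "climate": ClimateConfig,
    "dispersal": DispersalParams,
    "events": EventConfig,
    "curves": CurveConfig,
    "surveys": SurveyConfig,
    "reach": ReachConfig,
}

_TUPLE_FIELDS = {"domain", "band_fractions", "band_positions", "window_days",
                 "shapes", "durations_days", "steps", "events", "mean_link",
                 "refuge_holes"}


def _build(cls: type, data: dict[str, Any], path: str) -> Any:
    known = {f.name: f for f in fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown configuration field '{path}.{key}'")
        if key == "planted" and value is not None:
            value = _build(PlantedConfig, value or {}, f"{path}.planted")
        elif path == "climate" and key == "events" and value:
            from reefsources.synth.climate import ThermalEvent
            value = tuple(
                _build(ThermalEvent, ev or {}, f"climate.events[{i}]")
                for i, ev in enumerate(value))
        elif key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{path}': {exc}") from exc


def config_from_dict(doc: dict[str, Any]) -> RunConfig:
    kwargs: dict[str, Any] = {}
    for key, value in (doc or {}).items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build(_SECTION_TYPES[key], value or {}, key)
        elif key == "n_thermal_events":
            kwargs[key] = int(value)
        else:
            raise ConfigError(f"unknown configuration section '{key}'")
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    return config_from_dict(doc)


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(cfg)


def default_demo_config() -> RunConfig:
    """Bundled demo: a planted-truth seascape small enough to run on one
    CPU in minutes (50 reefs, 4 spawning events, 3 competency curves)."""
    return RunConfig(
        seascape=SeascapeConfig(n_reefs=50, n_regions=2,
                                planted=PlantedConfig(n_planted=8)),
        currents=CurrentsConfig(time_span_hours=24.0 * 50),
        dispersal=DispersalParams(n_runs=2, particles_per_run=120,
                                  diffusivity_m2_s=20.0),
        events=EventConfig(n_events=4, spacing_days=5.0),
        curves=CurveConfig(shapes=(2.0, 5.0, 12.0)),
        surveys=SurveyConfig(n_surveyed=50),
        reach=ReachConfig(durations_days=(1, 2, 5, 10, 20, 30),
                          steps=(1, 2, 3, 5)),
        climate=ClimateConfig(n_years=36),
    )
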