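"""Declarative run configuration with a strict schema.

A run is described by a single YAML (or JSON) document; unknown keys are
rejected with their full key path, and a loaded configuration round-trips
losslessly through :meth:`RunConfig.to_dict`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .moea import NSGAConfig
from .pacing import DEFAULT_DT_MS, DEFAULT_RECORD_DT_MS, StimulusProtocol


@dataclass
class OptimizerSettings:
    pop_size: int = 100
    max_evaluations: int = 10000
    eta_crossover: float = 20.0
    eta_mutation: float = 20.0
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # None → 1/p


@dataclass
class ProtocolSettings:
    amplitude_pA_per_pF: float = 20.0
    duration_ms: float = 2.0
    cycle_length_ms: float = 1000.0
    n_beats: int = 20


@dataclass
class SolverSettings:
    dt_ms: float = DEFAULT_DT_MS
    record_dt_ms: float = DEFAULT_RECORD_DT_MS
    ts_ms: float = 1.0


@dataclass
class RunConfig:
    """Validated, fully defaulted description of one experiment run."""

    scenario: int = 1
    configuration: str = "baseline"
    seeds: list[int] = field(default_factory=lambda: [0])
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)
    solver: SolverSettings = field(default_factory=SolverSettings)
    margin_mV: float = 5.0
    output_dir: str = "results"

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ConfigurationError(
                f"scenario: must be 1, 2 or 3, got {self.scenario}")
        if self.margin_mV <= 0:
            raise ConfigurationError(
                f"margin_mV: must be positive, got {self.margin_mV}")
        if not self.seeds:
            raise ConfigurationError("seeds: at least one seed is required")
        for name in ("amplitude_pA_per_pF", "duration_ms", "cycle_length_ms",
                     "n_beats"):
            if getattr(self.protocol, name) <= 0:
                raise ConfigurationError(f"protocol.{name}: must be positive")
        for name in ("pop_size", "max_evaluations", "eta_crossover",
                     "eta_mutation"):
            if getattr(self.optimizer, name) <= 0:
                raise ConfigurationError(f"optimizer.{name}: must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def stimulus_protocol(self) -> StimulusProtocol:
        p = self.protocol
        return StimulusProtocol(p.amplitude_pA_per_pF, p.duration_ms,
                                p.cycle_length_ms, p.n_beats)

    def nsga_config(self, seed: int = 0) -> NSGAConfig:
        o = self.optimizer
        return NSGAConfig(pop_size=o.pop_size,
                          max_evaluations=o.max_evaluations,
                          eta_crossover=o.eta_crossover,
                          eta_mutation=o.eta_mutation,
                          crossover_prob=o.crossover_prob,
                          mutation_prob=o.mutation_prob, seed=seed)


_SECTION_TYPES = {"optimizer": OptimizerSettings, "protocol": ProtocolSettings,
                  "solver": SolverSettings}


def _build(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if not isinstance(value, dict):
                raise ConfigurationError(f"{key}: must be a mapping")
            bad = set(value) - set(cls.__dataclass_fields__)
            if bad:
                raise ConfigurationError(
                    f"unknown key(s) under {key}: {sorted(bad)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigurationError(str(err)) from err


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; defaults fill gaps."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml", ""} \
        else json.loads(text)
    if data is None:  # empty file → all defaults
        data = {}
    return _build(data)
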