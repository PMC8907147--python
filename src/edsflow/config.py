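"""Run configuration: a single structured YAML file drives the workflow.

Sections: ``system`` (which toy preset or random spec to build), ``thermo``,
``exploration``, ``optimization``, ``production`` and top-level ``seed`` and
``start_mode``.  Every field has a default, so a minimal config is just an
empty file; unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .explore import ExplorationConfig
from .optimize import OptimizationSchedule
from .potentials import ThermoContext
from .toys import ToySystemSpec, benchmark_system, bottleneck_system, make_toy_system

__all__ = ["SystemConfig", "ProductionConfig", "RunConfig", "load_config"]


@dataclass
class SystemConfig:
    """Which end-state system to build: a named preset or a random spec."""

    preset: str = "benchmark"  # benchmark | bottleneck | random
    n_states: int = 5
    dimension: int = 1
    seed: int = 0

    def build(self):
        if self.preset == "benchmark":
            return benchmark_system()
        if self.preset == "bottleneck":
            return bottleneck_system()
        if self.preset == "random":
            return make_toy_system(
                ToySystemSpec(n_states=self.n_states, dimension=self.dimension, seed=self.seed)
            )
        raise ValueError(f"unknown system preset {self.preset!r}")


@dataclass
class ProductionConfig:
    n_steps: int = 40000
    exchange_interval: int = 20
    record_interval: int = 1
    discard_fraction: float = 0.0


@dataclass
class RunConfig:
    system: SystemConfig = field(default_factory=SystemConfig)
    thermo: ThermoContext = field(default_factory=ThermoContext)
    exploration: ExplorationConfig = field(default_factory=ExplorationConfig)
    optimization: OptimizationSchedule = field(default_factory=OptimizationSchedule)
    production: ProductionConfig = field(default_factory=ProductionConfig)
    rebalance_intensity_factor: float = 30.0
    start_mode: str = "SSM"
    seed: int = 1

    def validate(self) -> None:
        if self.start_mode not in ("SSM", "1SS"):
            raise ValueError("start_mode must be 'SSM' or '1SS'")
        if not (0.0 < self.exploration.s_min < 1.0):
            raise ValueError("exploration.s_min must lie in (0, 1)")
        if self.exploration.n_initial_s < 3:
            raise ValueError("exploration.n_initial_s must be >= 3")
        if self.production.n_steps < 1:
            raise ValueError("production.n_steps must be >= 1")
        if not (0 <= self.production.discard_fraction < 1):
            raise ValueError("production.discard_fraction must be in [0, 1)")
        if self.rebalance_intensity_factor <= 0:
            raise ValueError("rebalance_intensity_factor must be positive")


def _build(cls, data: dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    kwargs = dict(data)
    # tuples serialised as lists
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load a RunConfig from YAML; missing sections fall back to defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    if overrides:
        data = {**data, **overrides}
    known = {
        "system",
        "thermo",
        "exploration",
        "optimization",
        "production",
        "rebalance_intensity_factor",
        "start_mode",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = RunConfig(
        system=_build(SystemConfig, data.get("system", {}) or {}, "system"),
        thermo=_build(ThermoContext, data.get("thermo", {}) or {}, "thermo"),
        exploration=_build(ExplorationConfig, data.get("exploration", {}) or {}, "exploration"),
        optimization=_build(
            OptimizationSchedule, data.get("optimization", {}) or {}, "optimization"
        ),
        production=_build(ProductionConfig, data.get("production", {}) or {}, "production"),
        rebalance_intensity_factor=float(data.get("rebalance_intensity_factor", 30.0)),
        start_mode=str(data.get("start_mode", "SSM")),
        seed=int(data.get("seed", 1)),
    )
    cfg.validate()
    return cfg
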