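"""Run configuration: a typed, YAML-round-trippable description of every
stage parameter, with unknown keys rejected and a mandatory seed whenever a
stochastic stage is enabled."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ScenarioConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        target = _NESTED.get((cls, key))
        if target is not None and value is not None:
            if isinstance(value, dict) and target is not dict:
                value = _from_dict(target, value, f"{context}.{key}")
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class ScenarioConfig:
    """One simulated condition: the proteome dynamics model behind it.

    ``populations`` is a list of [weight, k_prime (N/m), u2_ref (Å²)]."""

    populations: list = field(
        default_factory=lambda: [[1.0, 0.35, 0.4]]
    )
    amplitude: float = 1.0e4
    background: float = 500.0
    t_ref: float = 278.0


@dataclass
class SimulateConfig:
    enabled: bool = True
    noise: bool = True
    scenarios: dict = field(
        default_factory=lambda: {
            # control/recovered share physiological dynamics; the stressed
            # condition mixes in an equal-weight softened subpopulation
            "control": {"populations": [[1.0, 0.35, 0.4]]},
            "stressed": {
                "populations": [[0.5, 0.35, 0.4], [0.5, 0.1, 1.2]]
            },
            "recovered": {"populations": [[1.0, 0.35, 0.4]]},
        }
    )


@dataclass
class ReduceConfig:
    transmission: float = 0.90


@dataclass
class MsdConfig:
    q_window: list = field(default_factory=lambda: [0.3, 1.5])
    q_unit: str = "invA"
    normalize_to_reference: bool = False


@dataclass
class ResilienceConfig:
    method: str = "analytic_propagation"
    n_boot: int = 1000


@dataclass
class KillSimConfig:
    n0: float = 1.0
    f_sensitive: float = 0.99
    k_fast: float = 2.0
    k_slow: float = 0.05
    noise_cv: float = 0.05
    t_max_days: float = 14.0
    n_points: int = 15


@dataclass
class LagSimConfig:
    lag_days: float = 3.0
    growth_rate: float = 0.05
    od0: float = 0.05
    noise_cv: float = 0.05
    span_days: float = 8.0
    dt_hours: float = 4.0
    n_boot: int = 500
    min_rate: float = 0.01


@dataclass
class KineticsConfig:
    kill: KillSimConfig = field(default_factory=KillSimConfig)
    lag: LagSimConfig = field(default_factory=LagSimConfig)


@dataclass
class CytometryConfig:
    planted_pi_fraction: float = 0.30
    n_events: int = 10_000
    pi_quantile: float = 0.995
    syto_quantile: float = 0.005


@dataclass
class RespirationConfig:
    basal_rate: float = 1.0
    stressed_rate: float = 0.25
    recovered_rate: float = 0.9
    o2_0: float = 200.0
    duration_min: float = 60.0
    noise_sd: float = 0.0


_ALL_STAGES = [
    "simulate",
    "reduce",
    "msd",
    "resilience",
    "kinetics",
    "cytometry",
    "respiration",
]


@dataclass
class RunConfig:
    """Top-level pipeline configuration (see module docstring)."""

    seed: int | None = None
    stages: list = field(default_factory=lambda: list(_ALL_STAGES))
    inputs: dict = field(default_factory=dict)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    reduce: ReduceConfig = field(default_factory=ReduceConfig)
    msd: MsdConfig = field(default_factory=MsdConfig)
    resilience: ResilienceConfig = field(default_factory=ResilienceConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    cytometry: CytometryConfig = field(default_factory=CytometryConfig)
    respiration: RespirationConfig = field(default_factory=RespirationConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s) {sorted(unknown)}")
        self.validate()

    def _stochastic(self) -> bool:
        if "simulate" in self.stages and self.simulate.enabled and self.simulate.noise:
            return True
        if "resilience" in self.stages and self.resilience.method == "bootstrap":
            return True
        if "kinetics" in self.stages and (
            self.kinetics.kill.noise_cv > 0
            or self.kinetics.lag.noise_cv > 0
            or self.kinetics.lag.n_boot > 0
        ):
            return True
        if "cytometry" in self.stages and "simulate" in self.stages:
            return True
        return False

    def validate(self):
        if self.seed is None and self._stochastic():
            raise ConfigError(
                "seed is mandatory when any stochastic stage is enabled"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data, "config")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )


_NESTED = {
    (RunConfig, "simulate"): SimulateConfig,
    (RunConfig, "reduce"): ReduceConfig,
    (RunConfig, "msd"): MsdConfig,
    (RunConfig, "resilience"): ResilienceConfig,
    (RunConfig, "kinetics"): KineticsConfig,
    (RunConfig, "cytometry"): CytometryConfig,
    (RunConfig, "respiration"): RespirationConfig,
    (KineticsConfig, "kill"): KillSimConfig,
    (KineticsConfig, "lag"): LagSimConfig,
}
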