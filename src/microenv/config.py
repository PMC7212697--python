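"""YAML configuration loading.

A run configuration is a single YAML file with up to three blocks::

    risk:                     # RiskConfig fields
      reference_mean: 10.0
      rr_incidence_per10: 1.08
      ...
    scenarios:                # name -> ScenarioSpec fields (sans name)
      base: {kind: baseline}
      who:  {kind: cap, cap_value: 10.0}
      necd: {kind: uniform_reduction, decrement: 3.6}
      noanth: {kind: remove_anthropogenic}
    engine:                   # optional engine keyword overrides
      p_male: 0.512
      incident_rule: diseased

The synthetic generator reads its own YAML whose keys mirror
:class:`~microenv.synthetic.SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .risk import RiskConfig
from .scenarios import ScenarioSpec
from .synthetic import SynthConfig


class ConfigError(ValueError):
    """Malformed configuration file."""


@dataclass
class RunConfig:
    risk: RiskConfig
    scenarios: dict[str, ScenarioSpec]
    engine: dict = field(default_factory=dict)

    def scenario(self, name: str) -> ScenarioSpec:
        try:
            return self.scenarios[name]
        except KeyError:
            raise ConfigError(
                f"unknown scenario {name!r}; defined: {sorted(self.scenarios)}"
            ) from None


def _load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    return data


def load_config(path) -> RunConfig:
    """Read a run configuration (risk + scenarios + engine blocks)."""
    data = _load_yaml(path)
    if "risk" not in data:
        raise ConfigError(f"{path}: missing 'risk' block")
    try:
        risk = RiskConfig(**data["risk"])
    except TypeError as exc:
        raise ConfigError(f"{path}: bad risk block: {exc}") from None
    scenarios = {"base": ScenarioSpec(name="base", kind="baseline")}
    for name, spec in (data.get("scenarios") or {}).items():
        try:
            scenarios[name] = ScenarioSpec(name=name, **(spec or {}))
        except TypeError as exc:
            raise ConfigError(f"{path}: bad scenario {name!r}: {exc}") from None
    engine = data.get("engine") or {}
    if not isinstance(engine, dict):
        raise ConfigError(f"{path}: 'engine' block must be a mapping")
    return RunConfig(risk=risk, scenarios=scenarios, engine=engine)


def load_synth_config(path) -> SynthConfig:
    """Read a synthetic-generator configuration."""
    data = _load_yaml(path)
    for key in ("pm25_range", "gfr_range"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return SynthConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
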