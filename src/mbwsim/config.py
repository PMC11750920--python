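"""Scenario configuration: validated, unit-suffixed, YAML/JSON round-trippable.

Key names carry explicit unit suffixes (``D_cm2_per_s``, ``T_s``, ...) so a
config file cannot silently drift units.  The defaults reproduce the
reference study setup: He-N2 at D = 0.6 cm^2/s, 4-s breaths at 250 ml/s
(500-ml tidal volume), 200 s of simulated washout at dt = 0.5 ms (Heun).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .model_builder import AsymmetrySpec, BreathingPattern
from .transport_solver import Gas

__all__ = ["Scenario", "load_scenario", "dump_scenario"]


class GasConfig(BaseModel):
    name: str = "He-N2"
    D_cm2_per_s: float = Field(0.6, gt=0)

    def to_gas(self) -> Gas:
        return Gas(self.name, self.D_cm2_per_s)


class PatternConfig(BaseModel):
    T_s: float = Field(4.0, gt=0)
    Q_hat_ml_per_s: float = Field(250.0, gt=0)
    duration_s: float = Field(200.0, gt=0)

    def to_pattern(self) -> BreathingPattern:
        return BreathingPattern(self.T_s, self.Q_hat_ml_per_s, self.duration_s)


class AsymmetryConfig(BaseModel):
    area: int = Field(ge=1, le=5)
    f_c: float = Field(gt=0.0, lt=2.0)

    def to_spec(self) -> AsymmetrySpec:
        return AsymmetrySpec(self.area, self.f_c)


class SolverConfig(BaseModel):
    dt_s: float = Field(5e-4, gt=0)
    scheme: str = "heun"
    snapshot_interval_s: float = Field(0.02, gt=0)

    @field_validator("scheme")
    @classmethod
    def _known_scheme(cls, v: str) -> str:
        if v not in ("heun", "euler"):
            raise ValueError(f"unknown scheme {v!r}")
        return v


class Scenario(BaseModel):
    """One washout run: gas, breathing, optional asymmetry, solver, output."""

    name: str = "symmetric"
    gas: GasConfig = GasConfig()
    pattern: PatternConfig = PatternConfig()
    asymmetry: AsymmetryConfig | None = None
    solver: SolverConfig = SolverConfig()
    output_dir: str = "mbwsim_out"


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from YAML (or JSON; YAML is a superset)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return Scenario.model_validate(data)


def dump_scenario(scenario: Scenario, path: str | Path | None = None) -> str:
    """Canonical YAML serialisation; parsing it back gives an equal scenario."""
    text = yaml.safe_dump(
        json.loads(scenario.model_dump_json()), sort_keys=True, default_flow_style=False
    )
    if path is not None:
        Path(path).write_text(text)
    return text
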