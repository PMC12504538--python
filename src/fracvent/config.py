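"""Project configuration and deterministic test fixtures.

A single YAML file drives the whole pipeline; every field defaults to
the nominal published study conditions, so an empty file is a complete,
valid configuration.  Unknown keys are rejected eagerly (no silent
typos) and all validation happens at load time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .control import ControllerGains, printed_gains_fixture
from .ladder import (
    LadderNetwork,
    LadderParameters,
    assemble_pseudo_state_space,
    build_ladder,
)
from .mittag_leffler import mittag_leffler
from .model import FractionalStateModel

__all__ = ["ProjectConfig", "load_config", "save_config", "make_toy_fixtures"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ModelSection(_Strict):
    r_ua: float = 0.2834
    c_ua: float = 0.0950
    alpha: float = 1.55
    n_stages: int = 24

    @field_validator("r_ua", "c_ua")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v):
        if not 0.0 < v < 2.0:
            raise ValueError(f"alpha must lie in (0, 2), got {v}")
        return v

    @field_validator("n_stages")
    @classmethod
    def _stages(cls, v):
        if v < 2:
            raise ValueError(f"n_stages must be >= 2, got {v}")
        return v

    def ladder_parameters(self) -> LadderParameters:
        return LadderParameters(
            r_ua=self.r_ua, c_ua=self.c_ua, alpha=self.alpha, n_stages=self.n_stages
        )


class DesignSection(_Strict):
    r: float = 200.0
    theta_deg: float = 5.0
    k_r: float = 500.0
    epsilon: float = 0.1
    observer_r: float | None = None  # None -> same as controller
    observer_theta_deg: float | None = None

    @field_validator("r", "k_r", "epsilon")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("theta_deg")
    @classmethod
    def _theta(cls, v):
        if not 0.0 < v <= 90.0:
            raise ValueError(f"theta_deg must lie in (0, 90], got {v}")
        return v


class SimulationSection(_Strict):
    dt: float = 1e-3
    t_end: float = 11.25
    memory: int | str = "full"
    rate: float = 16.0
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    flow_setpoint: float = 0.48
    expiration: str = "freeze"

    @field_validator("dt", "t_end", "rate", "flow_setpoint")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("expiration")
    @classmethod
    def _expiration(cls, v):
        if v not in ("freeze", "track", "leak"):
            raise ValueError(f"expiration must be freeze/track/leak, got {v!r}")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.t_end < self.dt:
            raise ValueError("t_end must be >= dt")
        if self.memory != "full" and (not isinstance(self.memory, int) or self.memory < 1):
            raise ValueError(f"memory must be 'full' or an integer >= 1, got {self.memory!r}")
        return self


class RobustnessSection(_Strict):
    perturbation_pct: float = 15.0
    n_draws: int = 100
    seed: int = 0

    @field_validator("perturbation_pct")
    @classmethod
    def _pct(cls, v):
        if not 0.0 <= v < 100.0:
            raise ValueError(f"perturbation_pct must lie in [0, 100), got {v}")
        return v

    @field_validator("n_draws")
    @classmethod
    def _draws(cls, v):
        if v < 1:
            raise ValueError(f"n_draws must be >= 1, got {v}")
        return v


class ProjectConfig(_Strict):
    model: ModelSection = ModelSection()
    design: DesignSection = DesignSection()
    simulation: SimulationSection = SimulationSection()
    robustness: RobustnessSection = RobustnessSection()
    output_dir: str = "fracvent_output"

    def content_hash(self) -> str:
        """Stable hash of the fully resolved configuration (for reports)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> ProjectConfig:
    """Load and validate a YAML configuration; missing file/keys use defaults."""
    if path is None:
        return ProjectConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return ProjectConfig()
    if not isinstance(data, dict):
        raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return ProjectConfig(**data)


def save_config(config: ProjectConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def make_toy_fixtures() -> dict:
    """Deterministic small instances for tests and examples.

    Contents: 1/2/3-stage ladders with their assembled models, a
    controllable 2x2 pair, the published-gain fixture, and
    Mittag-Leffler relaxation curves E_alpha(-t^alpha) on t in [0, 5]
    for alpha in {0.5, 1, 1.55}.
    """
    fixtures: dict = {}
    for n in (1, 2, 3):
        params = LadderParameters(n_stages=max(n, 2))
        net = build_ladder(params)
        if n == 1:  # single-stage ladder: series R-CPE branch
            net = LadderNetwork(
                resistances=net.resistances[:1], capacitances=net.capacitances[:1]
            )
        fixtures[f"ladder_{n}"] = net
        fixtures[f"model_{n}"] = assemble_pseudo_state_space(net, params.alpha)
    fixtures["controllable_pair"] = (
        np.array([[0.0, 1.0], [0.0, 0.0]]),
        np.array([[0.0], [1.0]]),
    )
    fixtures["printed_gains"] = printed_gains_fixture()
    t = np.linspace(0.0, 5.0, 51)
    fixtures["mittag_leffler_curves"] = {
        alpha: mittag_leffler(alpha, -(t**alpha)) for alpha in (0.5, 1.0, 1.55)
    }
    fixtures["mittag_leffler_time"] = t
    return fixtures


def nominal_model(config: ProjectConfig | None = None) -> tuple[FractionalStateModel, LadderNetwork]:
    """(model, network) for the configured — by default nominal — lung ladder."""
    cfg = config or ProjectConfig()
    params = cfg.model.ladder_parameters()
    net = build_ladder(params)
    return assemble_pseudo_state_space(net, params.alpha), net
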