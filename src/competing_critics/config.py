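"""Structured run configuration: YAML schema, validation, round-trip.

The schema mirrors the simulation surface: a learner-parameter block, a
task name, one optional block per task, and run sizes.  Unknown keys are
rejected (typo safety) and every bound violation names the offending
field.  Defaults reproduce the standard simulation setup: parameters
(alpha, epsilon, gamma, k+, k-) = (0.5, 0.3, 0, 0.9, 0.9), 100 trials
(80 for the two-stage task, 120 for the market task), 30,000 replicates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import CriticParams
from .engine import FULL_REPLICATES, SimulationConfig
from .environments import DeckScheme
from .rewards import MomentSpec

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsBlock(_Strict):
    alpha: float = Field(default=0.5, gt=0.0, le=1.0)
    epsilon: float = Field(default=0.3, ge=0.0, le=1.0)
    gamma: float = Field(default=0.0, ge=0.0, lt=1.0)
    k_plus: float = Field(default=0.9, ge=0.0, le=1.0)
    k_minus: float = Field(default=0.9, ge=0.0, le=1.0)

    def to_params(self) -> CriticParams:
        return CriticParams(**self.model_dump())


class StationaryBlock(_Strict):
    mu: float = 0.5
    sigma: float = Field(default=0.2, gt=0.0)
    skew: float = 0.0
    kurt: float = 2.5

    @model_validator(mode="after")
    def _feasible(self) -> "StationaryBlock":
        bound = self.skew**2 + 1.0
        if self.kurt < bound - 1e-12:
            raise ValueError(f"kurt = {self.kurt} violates kurt >= skew**2 + 1 = {bound}")
        return self

    def to_spec(self) -> MomentSpec:
        return MomentSpec(**self.model_dump())


class DeckBlock(_Strict):
    values: list[float]
    probs: list[float]


class IGTBlock(_Strict):
    scheme: dict[str, DeckBlock] | None = None

    def to_scheme(self) -> DeckScheme:
        if self.scheme is None:
            return DeckScheme()
        return DeckScheme(
            support={
                deck: (tuple(block.values), tuple(block.probs))
                for deck, block in self.scheme.items()
            }
        )


class TwoStageBlock(_Strict):
    p_common: float = Field(default=0.7, ge=0.0, le=1.0)
    reward_value: float = 1.0
    prob_bounds: tuple[float, float] = (0.25, 0.75)
    drift_sd: float = Field(default=0.025, ge=0.0)


class MarketBlock(_Strict):
    n_markets: int = Field(default=6, ge=1)
    trials_per_market: int = Field(default=20, ge=1)
    volatility: float = Field(default=0.05, gt=0.0)
    p0: float = Field(default=100.0, gt=0.0)


_TASK_TRIALS = {"stationary": 100, "igt": 100, "two_stage": 80, "market": 120}


class RunConfig(_Strict):
    """Top-level run configuration (see module docstring for defaults)."""

    task: Literal["stationary", "igt", "two_stage", "market"] = "stationary"
    params: ParamsBlock = Field(default_factory=ParamsBlock)
    stationary: StationaryBlock = Field(default_factory=StationaryBlock)
    igt: IGTBlock = Field(default_factory=IGTBlock)
    two_stage: TwoStageBlock = Field(default_factory=TwoStageBlock)
    market: MarketBlock = Field(default_factory=MarketBlock)
    trials: int | None = Field(default=None, ge=1)
    replicates: int = Field(default=FULL_REPLICATES, ge=1)
    seed: int = 0
    track_neutral: bool = True

    def resolved_trials(self) -> int:
        return self.trials if self.trials is not None else _TASK_TRIALS[self.task]

    def task_kwargs(self) -> dict:
        if self.task == "stationary":
            return {"spec": self.stationary.to_spec()}
        if self.task == "igt":
            return {"scheme": self.igt.to_scheme()}
        if self.task == "two_stage":
            return self.two_stage.model_dump()
        return self.market.model_dump()

    def to_simulation(self) -> SimulationConfig:
        return SimulationConfig(
            params=self.params.to_params(),
            task=self.task,
            task_kwargs=self.task_kwargs(),
            trials=self.resolved_trials(),
            replicates=self.replicates,
            seed=self.seed,
            track_neutral=self.track_neutral,
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw or {})


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (load -> dump -> load is identity)."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
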