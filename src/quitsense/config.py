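"""Run configuration: one YAML document, one mandatory seed, strict keys.

A single global seed drives every stochastic stage; the simulator fans it
out into independent per-participant streams, so any module can be re-run
in isolation from the provenance record alone.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .ema import StudyCalendar, WakingWindow
from .engine import RiskConfig
from .errors import ConfigurationError
from .simulate import ARMS, SimConfig


class RunConfig(BaseModel):
    """Everything a full simulate-decide-analyze run needs.

    ``sim`` holds overrides for :class:`~quitsense.simulate.SimConfig`
    (its seed is always the global seed).  Unknown keys anywhere are
    rejected.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int
    calendar: StudyCalendar = StudyCalendar()
    window: WakingWindow = WakingWindow()
    risk: RiskConfig = RiskConfig()
    sim: dict = {}
    arms: tuple[str, ...] = ARMS
    bank_path: Optional[str] = None

    @model_validator(mode="after")
    def _validate_sim(self) -> "RunConfig":
        self.sim_config()  # raises on unknown/invalid sim keys
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms {sorted(unknown)}")
        return self

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.pop("seed", None)
        return SimConfig(seed=self.seed, **sim)


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        err = exc.errors()[0]
        path = ".".join(str(p) for p in err["loc"]) or "config"
        raise ConfigurationError(f"{path}: {err['msg']}") from exc


def dump_config(config: RunConfig) -> dict:
    """The effective configuration with all defaults applied (YAML-safe)."""
    return config.model_dump(mode="json")


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(config), fh, sort_keys=True)
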