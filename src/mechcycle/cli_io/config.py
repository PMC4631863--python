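"""TOML run configuration with strict validation (unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

__all__ = ["ThermoSection", "ProbitSection", "RunConfig", "load_config", "config_hash"]


class ThermoSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gas_constant: float = Field(default=1.98719e-3, gt=0)
    temperature: float = Field(default=298.15, gt=0)


class ProbitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    printed_sign: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    thermo: ThermoSection = ThermoSection()
    probit: ProbitSection = ProbitSection()
    classifier_threshold: float = Field(default=1.5, gt=1)
    alpha: float = Field(default=0.01, gt=0, lt=1)
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from TOML; None gives defaults."""
    if path is None:
        return RunConfig()
    with Path(path).open("rb") as fh:
        data = tomllib.load(fh)
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration, for provenance logging."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
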