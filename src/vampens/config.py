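"""Run configuration: YAML-backed, schema-validated, defaulted.

Defaults reproduce the standard protocol: ensembles of 20 models over 20
random 90/10 splits with 3 initializations each, lag of 250 saved frames
(25 ns at the 0.1 ns save interval), cross-system match threshold T_e = 6,
saliency averaged over 10,000 frames, and a free-energy surface from a KDE
on 10% of the frames.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["SyntheticConfig", "SystemInput", "RunConfig", "validate_config", "config_hash"]


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_trajectories: int = Field(10, ge=1)
    frames_per_trajectory: int = Field(10_000, ge=2)
    noise_sigma: float = Field(1.0, gt=0)
    seed: int = 0


class SystemInput(BaseModel):
    """One system's data source: an HDF5 feature file or a synthetic spec."""

    model_config = ConfigDict(extra="forbid")

    label: str = "system"
    features_path: str | None = None
    synthetic: SyntheticConfig | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.features_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of features_path or synthetic")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    output_dir: str = "vampens_run"
    systems: list[SystemInput] = Field(default_factory=lambda: [SystemInput(synthetic=SyntheticConfig())])

    # featurization
    feature_mode: str = "min-heavy-atom"

    # soft-MSM ensemble
    n_states: int = Field(3, ge=2)
    lag_steps: int = Field(250, ge=1)
    n_models: int = Field(20, ge=1)
    inits_per_split: int = Field(3, ge=1)
    train_fraction: float = Field(0.9, gt=0, lt=1)
    hidden: list[int] = Field(default_factory=lambda: [100, 100, 100, 100])
    activation: str = "tanh"
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(1024, ge=8)
    max_epochs: int = Field(100, ge=1)
    patience: int = Field(10, ge=0)

    # cross-system alignment
    threshold: float = 6.0

    # saliency
    gradient_frames: int = Field(10_000, ge=1)

    # free-energy surface
    fes_fraction: float = Field(0.1, gt=0, le=1)
    fes_grid: int = Field(100, ge=10)

    @model_validator(mode="after")
    def _check(self):
        if self.activation not in ("tanh", "selu"):
            raise ValueError("activation must be 'tanh' or 'selu'")
        if self.feature_mode not in ("min-heavy-atom", "c-alpha"):
            raise ValueError("feature_mode must be 'min-heavy-atom' or 'c-alpha'")
        if not 1 <= len(self.systems) <= 2:
            raise ValueError("one or two systems per run")
        labels = [s.label for s in self.systems]
        if len(set(labels)) != len(labels):
            raise ValueError("system labels must be distinct")
        return self


def validate_config(raw_text: str) -> RunConfig:
    """Parse and validate a YAML run configuration; '' yields all defaults."""
    data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ValueError(f"invalid config at '{loc}': {first['msg']}") from err


def config_hash(config: RunConfig) -> str:
    """Stable digest of the full (defaulted) configuration."""
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
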