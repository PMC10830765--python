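"""Experiment configuration: schema validation, defaults, provenance.

Configurations are plain YAML/JSON mappings validated into a typed model
before any computation starts; unknown keys are rejected so typos fail
loudly. Every output artifact gets a JSON sidecar carrying the config
hash and seed sufficient to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import List

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .features import ATLAS_SIZES

__all__ = ["ExperimentConfig", "validate_config", "config_hash", "write_sidecar"]


class ExperimentConfig(BaseModel):
    """Typed, schema-checked experiment configuration."""

    model_config = ConfigDict(extra="forbid")

    atlases: List[str] = ["desikan-killiany", "destrieux", "glasser"]
    metrics: List[str] = ["mahalanobis", "taxicab"]
    taus: List[float] = [0.0, 0.6, 0.7, 0.8]
    normalizations: List[str] = ["none", "proportional", "residual"]
    tasks: List[str] = ["RR_vs_PP"]
    k: int = 5
    seed: int = 0
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 16
    patience: int = 20
    class_weights: bool = False
    out_dir: str = "results"

    @field_validator("atlases")
    @classmethod
    def _known_atlas(cls, v):
        for a in v:
            if a not in ATLAS_SIZES and not a.isdigit():
                raise ValueError(
                    f"unknown atlas {a!r}; choose from {sorted(ATLAS_SIZES)} "
                    "or an integer region count"
                )
        return v

    @field_validator("metrics")
    @classmethod
    def _known_metric(cls, v):
        for m in v:
            if m not in ("mahalanobis", "taxicab"):
                raise ValueError(f"unknown metric {m!r}")
        return v

    @field_validator("taus")
    @classmethod
    def _tau_domain(cls, v):
        for t in v:
            if not (0.0 <= t < 1.0):
                raise ValueError(f"tau must be in [0, 1), got {t}")
        return v

    @field_validator("normalizations")
    @classmethod
    def _known_mode(cls, v):
        for m in v:
            if m not in ("none", "proportional", "residual"):
                raise ValueError(f"unknown normalization mode {m!r}")
        return v

    def atlas_sizes(self) -> List[int]:
        return [ATLAS_SIZES.get(a, None) or int(a) for a in self.atlases]


def validate_config(raw) -> ExperimentConfig:
    """YAML/JSON text, mapping, or path -> validated ExperimentConfig."""
    if isinstance(raw, ExperimentConfig):
        return raw
    if isinstance(raw, (str, Path)):
        p = Path(raw)
        text = p.read_text() if p.exists() else str(raw)
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    return ExperimentConfig(**raw)


def config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_sidecar(path, cfg: ExperimentConfig = None, seed=None, **extra) -> None:
    """JSON sidecar with enough provenance to regenerate the artifact."""
    meta = {
        "created": datetime.now(timezone.utc).isoformat(),
        **extra,
    }
    if cfg is not None:
        meta["config_hash"] = config_hash(cfg)
        meta["config"] = cfg.model_dump()
    if seed is not None:
        meta["seed"] = seed
    Path(path).write_text(json.dumps(meta, indent=2))
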