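"""Run configuration: validated defaults shared by every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """Thresholds and defaults for a pipeline run.

    Defaults mirror the study's printed constants: Bliss-index cutoff
    0.15 with a 12% flag fraction (the 3-of-25 rule), efflux-ratio
    cutoff 2, insert area 0.7 cm^2, DEG filter at 2-fold / FDR 0.05.
    """

    bi_threshold: float = Field(0.15, gt=0)
    flag_fraction: float = Field(0.12, gt=0, lt=1)
    er_cutoff: float = Field(2.0, gt=0)
    area_cm2: float = Field(0.7, gt=0)
    deg_fold_threshold: float = Field(2.0, gt=0)
    deg_fdr_threshold: float = Field(0.05, gt=0, lt=1)
    outlier_z_cutoff: float = Field(3.0, gt=0)
    pseudocount: float = Field(0.5, gt=0)
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("log_level")
    @classmethod
    def _known_level(cls, v: str) -> str:
        if v.upper() not in {"DEBUG", "INFO", "WARNING", "ERROR"}:
            raise ValueError(f"unknown log level {v!r}")
        return v.upper()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        """Stable hash of the full configuration (written into outputs)."""
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
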