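"""Pipeline configuration: panel, gate tree, calibration, analysis knobs.

Validated with pydantic; `load_config` reads a JSON document and reports
every failing field at once. Defaults encode the method's standing
choices: 500 equally spaced bins for quadratic entropy, mixture component
counts 1–9 with BIC selection, and the QE = 0.7 low/high heterogeneity
boundary.
"""

from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "AnalysisParams",
    "CalibrationConfig",
    "ConfigError",
    "GateSpec",
    "PipelineConfig",
    "TargetCriteriaConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration; message lists all failing fields."""


class GateSpec(BaseModel):
    """One node of the hierarchical gate tree.

    A node with a ``marker`` tests events against ``threshold`` in the
    stated ``direction`` ("positive" means intensity >= threshold). A node
    without a marker matches everything (the root, or an explicit
    catch-all child such as the residual "other" population). Nodes
    without children are leaves and must carry a population ``label``.
    """

    model_config = ConfigDict(extra="forbid")

    marker: Optional[str] = None
    threshold: Optional[float] = None
    direction: Optional[Literal["negative", "positive"]] = None
    label: Optional[str] = None
    children: list["GateSpec"] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "GateSpec":
        if self.marker is not None and (self.threshold is None or self.direction is None):
            raise ValueError(f"gate on {self.marker!r} needs both threshold and direction")
        if not self.children and self.label is None:
            raise ValueError("leaf gate nodes must carry a population label")
        return self


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beads_path: Optional[str] = None
    receptors_per_fluorophore: float = Field(default=1.0, gt=0)
    background_path: Optional[str] = None  # optional unstained/isotype control


class AnalysisParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bins: int = Field(default=500, ge=2)
    k_min: int = Field(default=1, ge=1, le=9)
    k_max: int = Field(default=9, ge=1, le=9)
    qe_threshold: float = Field(default=0.7, gt=0)
    n_restarts: int = Field(default=5, ge=1)
    min_cells: int = Field(default=50, ge=1)
    bootstrap_samples: int = Field(default=500, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "AnalysisParams":
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        return self


class TargetCriteriaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    availability_fraction_min: float = Field(default=0.70, gt=0, le=1)
    availability_receptors_min: float = Field(default=6_000.0, gt=0)
    qe_max: float = Field(default=0.7, gt=0)
    specificity_fold_min: float = Field(default=2.0, gt=0)
    minority_weight_max: float = Field(default=0.10, gt=0, le=1)
    minority_fold_min: float = Field(default=10.0, gt=0)


class PipelineConfig(BaseModel):
    """Complete run description for the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    sample_id: str = "sample"
    events_path: Optional[str] = None
    panel: dict[str, str] = Field(default_factory=dict)
    gates: GateSpec
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)
    criteria: TargetCriteriaConfig = Field(default_factory=TargetCriteriaConfig)
    # healthy-tissue reference geometric means, marker -> receptors/cell
    reference: dict[str, float] = Field(default_factory=dict)
    seed: int = Field(default=0, ge=0)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, separators=(",", ":"))


def load_config(path) -> PipelineConfig:
    """Parse and validate a JSON pipeline configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.read()
    try:
        return PipelineConfig.model_validate_json(raw)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration:\n" + "\n".join(lines)) from None
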