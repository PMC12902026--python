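"""Pipeline configuration: pydantic-validated YAML with strict keys.

Unknown keys are rejected before any stage runs, so a typo in a config file
fails fast instead of silently using a default.
"""

from __future__ import annotations

from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenerateConfig(_Strict):
    n_train_per_class: int = Field(80, ge=0)
    n_test_per_class: int = Field(40, ge=0)
    image_size: int = Field(64, ge=64)
    preset: str = "separable"  # "separable" | "default"

    @field_validator("preset")
    @classmethod
    def _preset(cls, v):
        if v not in ("separable", "default"):
            raise ValueError("preset must be 'separable' or 'default'")
        return v


class FilterStageConfig(_Strict):
    n_train_per_class: int = Field(60, ge=0)
    n_test_per_class: int = Field(30, ge=0)
    w_b: float = Field(0.5, ge=0)
    w_z: float = Field(0.5, ge=0)
    blur_kernel: int = 5
    threshold_mode: str = "otsu"
    fixed_threshold: float = 128.0


class ModelConfig(_Strict):
    backbone: str = "tinycnn"
    loss: str = "triplet"
    input_size: int = 64


class TrainingConfig(_Strict):
    epochs: int = Field(10, ge=0)
    batch_size: Optional[int] = None
    lr0: float = 1e-4
    margin: float = 0.2
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    split_fraction: float = 0.8


class ClassificationConfig(_Strict):
    k: int = Field(5, ge=1)
    classifier: str = "knn"  # "knn" | "centroid"


class GradcamConfig(_Strict):
    n_examples: int = Field(4, ge=0)
    opacity: float = Field(0.5, ge=0, le=1)


class ReportingConfig(_Strict):
    backbones: List[str] = ["tinycnn"]
    losses: List[str] = ["triplet", "bce", "focal"]


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/demo"
    generate: GenerateConfig = GenerateConfig()
    filter: FilterStageConfig = FilterStageConfig()
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()
    classification: ClassificationConfig = ClassificationConfig()
    gradcam: GradcamConfig = GradcamConfig()
    reporting: ReportingConfig = ReportingConfig()


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load and validate a YAML config; keyword overrides win over the file."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        if "." in key:
            section, leaf = key.split(".", 1)
            data.setdefault(section, {})[leaf] = value
        else:
            data[key] = value
    return PipelineConfig.model_validate(data)
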