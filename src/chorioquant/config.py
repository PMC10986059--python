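"""Validated run configuration (YAML-backed, pydantic models).

One config object drives a full simulate → quantify → analyze run; every
default is serialized into the run manifest so each run is self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class SceneConfig(BaseModel):
    image_width_px: int = Field(1280, gt=0)
    image_height_px: int = Field(256, gt=0)
    lateral_um_per_px: float = Field(5.86, gt=0)
    axial_um_per_px: float = Field(3.9, gt=0)
    choroid_thickness_um: float = Field(270.0, gt=0)
    target_lumen_fraction: float = Field(0.62, ge=0, le=1)
    vessel_radius_min_um: float = Field(15.0, gt=0)
    vessel_radius_max_um: float = Field(70.0, gt=0)
    stroma_mean: float = 200.0
    lumen_mean: float = 40.0
    speckle_shape: float = Field(4.0, gt=0)


class AngioConfig(BaseModel):
    image_size_px: int = Field(512, gt=0)
    lateral_um_per_px: float = Field(5.86, gt=0)
    target_fd_fraction: float = Field(0.08, ge=0, le=1)
    perfused_mean: float = 180.0
    deficit_mean: float = 5.0
    noise_sd: float = Field(5.0, ge=0)
    shadow_attenuation: float = Field(1.0, ge=0, le=1)
    projection_vessel_width_um: float = Field(0.0, ge=0)


class CohortConfig(BaseModel):
    n_per_group: int = Field(30, ge=2)


class NiblackConfig(BaseModel):
    window_px: int = Field(201, ge=3)
    k: float = -0.18


class FdThresholdConfig(BaseModel):
    sigma_ref: float = Field(30.0, gt=0)
    multiplier: float = Field(1.5, gt=0)


class SlabConfig(BaseModel):
    offset_um: float = Field(0.0, ge=0)
    thickness_um: float = Field(20.0, gt=0)


class RunConfig(BaseModel):
    """Top-level configuration of a pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    n_imaging_subjects: int = Field(2, ge=1)
    visits_min: list[int] = Field(default_factory=lambda: [20, 40, 60])
    scene: SceneConfig = Field(default_factory=SceneConfig)
    angio: AngioConfig = Field(default_factory=AngioConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    niblack: NiblackConfig = Field(default_factory=NiblackConfig)
    fd_threshold: FdThresholdConfig = Field(default_factory=FdThresholdConfig)
    slab: SlabConfig = Field(default_factory=SlabConfig)
    reference_al_mm: float = Field(24.385, gt=15, lt=40)
    roi_width_mm: float = Field(6.0, gt=0)
    circle_diameter_mm: float = Field(2.5, gt=0)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load and validate a YAML config; field-named errors on failure."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
            data = raw
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise ConfigError(f"invalid config field(s): {fields}") from exc
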