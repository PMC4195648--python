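"""Pipeline configuration: every stage default in one validated object.

Unknown keys are rejected so a typo in a config file cannot silently fall
back to a default. The single global ``seed`` fans out to per-stage seeds
through ``numpy.random.SeedSequence([seed, stage_index])``; the only
stochastic stage is the optional FCM initialization jitter, so default runs
are fully deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .errors import ValidationError


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessConfig(_StrictModel):
    low_percentile: float = 0.5
    high_percentile: float = 99.5
    bg_threshold: float = Field(default=0.05, ge=0.0, le=1.0)
    diffusion_iterations: int = Field(default=15, ge=0)
    diffusion_kappa: float = Field(default=0.1, gt=0)
    diffusion_step: float = Field(default=0.2, gt=0, le=0.25)
    conductance_form: str = "exponential"
    edge_gain: float = Field(default=1.0, ge=0)
    edge_gain_sigma: float = Field(default=1.0, gt=0)


class InitConfig(_StrictModel):
    shrink_scale: float = Field(default=0.80, gt=0)
    adaptive_scale: bool = True  # derive scale from the binary mask size
    wall_clearance: float = Field(default=4.5, gt=0)
    center_mode: str = "slice_center"
    band_width: float = Field(default=10.0, gt=0)


class SnakeConfig(_StrictModel):
    local_radius: int = Field(default=3, ge=1)
    curvature_weight: float = Field(default=0.2, ge=0)
    balloon_weight: float = Field(default=0.1, ge=0)
    edge_sigma: float = Field(default=1.5, ge=0)
    edge_scale: float = Field(default=1.0, gt=0)
    area_tol: float = Field(default=10.0, gt=0)
    check_interval: int = Field(default=5, ge=1)
    max_iters: int = Field(default=500, ge=0)
    dt: float = Field(default=0.35, gt=0, le=0.5)
    reinit_every: int = Field(default=20, ge=0)


class FCMConfig(_StrictModel):
    sat_classes: int = Field(default=3, ge=1)
    vat_classes: int = Field(default=5, ge=1)
    fuzzifier_m: float = Field(default=2.0, gt=1)
    tol: float = Field(default=1e-5, gt=0)
    max_iter: int = Field(default=300, ge=1)
    intensity_gap: float = Field(default=0.15, ge=0)
    pooled: bool = True  # cluster voxels pooled across slices
    perturb_init: bool = False  # seed-jittered centroid initialization


class StripConfig(_StrictModel):
    skin_depth: float = Field(default=2.0, ge=0)
    wall_depth: float = Field(default=1.0, ge=0)


class QuantConfig(_StrictModel):
    density_g_per_ml: float = Field(default=0.9, gt=0)


class PipelineConfig(_StrictModel):
    """Full configuration of the segmentation pipeline."""

    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    init: InitConfig = Field(default_factory=InitConfig)
    snake: SnakeConfig = Field(default_factory=SnakeConfig)
    fcm: FCMConfig = Field(default_factory=FCMConfig)
    strip: StripConfig = Field(default_factory=StripConfig)
    quant: QuantConfig = Field(default_factory=QuantConfig)
    slice_start: int | None = None  # index range standing in for L1-L5
    slice_stop: int | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        try:
            return cls.model_validate(data)
        except Exception as exc:  # surface pydantic details as our error type
            raise ValidationError(f"invalid pipeline config {path}: {exc}") from exc

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
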