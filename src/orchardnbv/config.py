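"""Validated run configuration for the CLI and pipeline helpers.

One YAML document collects every tunable of the stack — camera intrinsics,
Gaussian-field fitting, occlusion quadrature, planner, NMS, scene generator
and mock-detector noise — validated up front (pydantic) before any
computation runs. ``RunConfig.model_json_schema()`` exports the schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .gaussians import DEFAULT_NI, EXCLUSION_FACTOR
from .geometry import CameraModel, look_at
from .planner import PlannerConfig, ReachableRegion
from .synthetic import MockDetectorConfig, SceneConfig


class CameraSection(BaseModel):
    fx: float = Field(500.0, gt=0)
    fy: float = Field(500.0, gt=0)
    u0: float = Field(320.0, ge=0)
    v0: float = Field(240.0, ge=0)
    width: int = Field(640, gt=0)
    height: int = Field(480, gt=0)

    @model_validator(mode="after")
    def _principal_point_inside(self):
        if not (self.u0 < self.width and self.v0 < self.height):
            raise ValueError("principal point must lie inside the image")
        return self

    def build(self) -> CameraModel:
        return CameraModel(self.fx, self.fy, self.u0, self.v0, self.width, self.height)


class FieldSection(BaseModel):
    voxel_size: float = Field(0.05, gt=0)
    min_points: int = Field(5, ge=1)
    cov_scale: float = Field(1.0, gt=0)


class OcclusionSection(BaseModel):
    ni: int = Field(DEFAULT_NI, ge=2)
    exclusion_factor: float = Field(EXCLUSION_FACTOR, gt=0)
    normalize: Literal["eligible", "scene"] = "eligible"


class PlannerSection(BaseModel):
    occlusion_threshold: float = Field(0.05, gt=0)
    iteration_threshold: int = Field(50, ge=1)
    step_size: float = Field(0.05, gt=0)
    fd_step: float = Field(1e-3, gt=0)
    ig_epsilon: float = Field(1e-3, gt=0)
    n_restarts: int = Field(4, ge=1)
    n_candidates: int = Field(32, ge=1)

    def build(self, ni: int, exclusion_factor: float, seed: int) -> PlannerConfig:
        return PlannerConfig(
            occlusion_threshold=self.occlusion_threshold,
            iteration_threshold=self.iteration_threshold,
            step_size=self.step_size,
            fd_step=self.fd_step,
            ig_epsilon=self.ig_epsilon,
            n_restarts=self.n_restarts,
            n_candidates=self.n_candidates,
            ni=ni,
            exclusion_factor=exclusion_factor,
            seed=seed,
        )


class RegionSection(BaseModel):
    kind: Literal["box", "shell"] = "box"
    lo: list[float] = Field(default=[-0.6, -1.6, 0.9])
    hi: list[float] = Field(default=[0.6, -0.7, 1.5])
    center: Optional[list[float]] = None
    r_min: float = 0.0
    r_max: float = 0.0
    z_min: Optional[float] = None

    def build(self) -> ReachableRegion:
        if self.kind == "box":
            return ReachableRegion(kind="box", lo=np.array(self.lo), hi=np.array(self.hi))
        return ReachableRegion(
            kind="shell",
            center=np.array(self.center),
            r_min=self.r_min,
            r_max=self.r_max,
            z_min=self.z_min,
        )


class SceneSection(BaseModel):
    n_fruits: int = Field(9, ge=1)
    crown_center: list[float] = Field(default=[0.0, 0.0, 1.2])
    crown_radius: float = Field(0.35, gt=0)
    diameter_mean: float = Field(0.075, gt=0)
    diameter_sd: float = Field(0.005, ge=0)
    fruit_class: int = 0
    n_branches: int = Field(6, ge=0)
    branch_radius: float = Field(0.02, gt=0)
    n_leaves: int = Field(25, ge=0)
    leaf_radius: float = Field(0.05, gt=0)
    min_separation: float = Field(0.02, ge=0)
    density: float = Field(2.0e4, gt=0)
    noise_sigma: float = Field(0.001, ge=0)

    def build(self) -> SceneConfig:
        return SceneConfig(
            n_fruits=self.n_fruits,
            crown_center=tuple(self.crown_center),
            crown_radius=self.crown_radius,
            diameter_mean=self.diameter_mean,
            diameter_sd=self.diameter_sd,
            fruit_class=self.fruit_class,
            n_branches=self.n_branches,
            branch_radius=self.branch_radius,
            n_leaves=self.n_leaves,
            leaf_radius=self.leaf_radius,
            min_separation=self.min_separation,
            density=self.density,
            noise_sigma=self.noise_sigma,
        )


class DetectorSection(BaseModel):
    sigma_p: float = Field(0.003, ge=0)
    sigma_d: float = Field(0.002, ge=0)
    beta: float = Field(2.0, ge=0)
    o_miss: float = Field(0.8, gt=0, le=1)
    conf_sigma: float = Field(0.02, ge=0)

    def build(self) -> MockDetectorConfig:
        return MockDetectorConfig(
            sigma_p=self.sigma_p, sigma_d=self.sigma_d, beta=self.beta,
            o_miss=self.o_miss, conf_sigma=self.conf_sigma,
        )


class RunConfig(BaseModel):
    """Every tunable of the pipeline, in one validated document."""

    seed: int = 0
    nms_threshold: float = Field(0.25, gt=0, le=1)
    tau: float = Field(0.005, gt=0)
    initial_camera_position: list[float] = Field(default=[0.0, -1.2, 1.2])
    camera: CameraSection = Field(default_factory=CameraSection)
    field: FieldSection = Field(default_factory=FieldSection)
    occlusion: OcclusionSection = Field(default_factory=OcclusionSection)
    planner: PlannerSection = Field(default_factory=PlannerSection)
    region: RegionSection = Field(default_factory=RegionSection)
    scene: SceneSection = Field(default_factory=SceneSection)
    detector: DetectorSection = Field(default_factory=DetectorSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def planner_config(self) -> PlannerConfig:
        return self.planner.build(
            self.occlusion.ni, self.occlusion.exclusion_factor, self.seed
        )

    def initial_pose(self):
        return look_at(
            np.array(self.initial_camera_position), np.array(self.scene.crown_center)
        )
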