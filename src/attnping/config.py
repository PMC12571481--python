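"""Validated pipeline configuration (YAML-backed).

A :class:`PipelineConfig` collects the simulation design, the ground-truth
effect sizes, and the analysis parameters, and is validated with pydantic
before any stage runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .synthgen import EffectParams, SimConfig


class SimBlock(BaseModel):
    n_subjects_per_session: int = 20
    n_shared_subjects: int = 14
    n_voxels: int = 100
    rois: list[str] = ["V1", "EVC", "IPS", "PFC"]
    n_attention_runs: int = 6
    n_perception_runs: int = 3
    trials_per_attention_run: int = 40
    trials_per_perception_run: int = 40
    p_long_delay: float = Field(0.8, ge=0.0, le=1.0)
    tr_seconds: float = Field(2.0, gt=0.0)

    def to_sim_config(self, seed: int) -> SimConfig:
        return SimConfig(seed=seed, rois=tuple(self.rois), **self.model_dump(exclude={"rois"}))


class EffectBlock(BaseModel):
    beta_sens: float = 1.0
    beta_att: float = 1.0
    lam: dict[str, float] | None = None
    lam_default: float = Field(0.6, ge=0.0, le=1.0)
    gamma_target: float = 1.0
    gamma_distractor: float = 0.3
    g: float = Field(0.0, ge=0.0)
    eta_sd: float = 0.15
    ping_gain_jitter_sd: float = 0.5
    propensity_sd: float = 0.25
    b_rt: float = 0.3
    rt_trial_slope: float = 0.25
    rt0: float = 0.9
    rt_noise_sd: float = 0.15
    accuracy_mean: float = Field(0.75, gt=0.0, lt=1.0)
    accuracy_sd: float = 0.05
    noise_scale: float = Field(1.0, gt=0.0)
    n_noise_components: int = Field(3, ge=0)
    noise_component_scale: float = Field(0.5, ge=0.0)

    def to_effect_params(self) -> EffectParams:
        return EffectParams(**self.model_dump())


class AnalysisBlock(BaseModel):
    shrinkage: float = Field(0.1, ge=0.0, le=1.0)
    window: tuple[float, float] = (4.0, 6.0)
    n_perm: int = Field(200, ge=1)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    quantile: float = Field(0.25, gt=0.0, le=0.5)
    min_run_accuracy: float = Field(0.5, ge=0.0, le=1.0)

    @field_validator("window")
    @classmethod
    def _window_ordered(cls, v):
        if v[1] <= v[0]:
            raise ValueError("window end must exceed window start")
        return v


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: Path = Path("attnping_out")
    sim: SimBlock = SimBlock()
    effects: EffectBlock = EffectBlock()
    analysis: AnalysisBlock = AnalysisBlock()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as f:
            yaml.safe_dump(data, f, sort_keys=True)
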