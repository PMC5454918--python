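"""Validated pipeline configuration (YAML) with per-module parameter blocks.

Unknown keys are rejected at load time; every block's defaults are the
module defaults, so an empty config describes the standard analysis
(100 nm / 10-point DBSCAN, 10-nm shells, 17-mer probes, ...).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LocalizerConfig(_Block):
    stack: str | None = None
    channel: str = "points"
    pixel_size_nm: float = Field(100.0, gt=0)
    roi_side: int = Field(7, ge=3)
    threshold_factor: float = Field(4.0, gt=0)

    @field_validator("roi_side")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("roi_side must be odd")
        return v


class RendererConfig(_Block):
    mode: str = "density"
    pixel_size_nm: float = Field(10.0, gt=0)
    radius_nm: float = Field(1000.0, gt=0)
    gauss_sigma_nm: float = Field(50.0, gt=0)

    @field_validator("mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("pointillist", "density", "localization"):
            raise ValueError("mode must be pointillist, density or localization")
        return v


class ClusterConfig(_Block):
    points: str | None = None
    channel: str = "alu"
    radius_nm: float = Field(100.0, gt=0)
    min_points: int = Field(10, ge=1)


class ShellsConfig(_Block):
    targets_channel: str = "het"
    shell_width_nm: float = Field(10.0, gt=0)
    max_radius_nm: float = Field(1000.0, gt=0)


class ProbeConfig(_Block):
    genome: str | None = None
    bed: str | None = None
    consensus: str | None = None
    k: int = Field(17, ge=1)
    strand: str = "both"
    specificity_floor: float = Field(0.99, ge=0, le=1)

    @field_validator("strand")
    @classmethod
    def _strand(cls, v: str) -> str:
        if v not in ("forward", "both"):
            raise ValueError("strand must be 'forward' or 'both'")
        return v


class DoseConfig(_Block):
    counts: str | None = None
    per_cell: bool = False


class SimulateConfig(_Block):
    kind: str = "nucleus"
    n_clusters: int = Field(200, ge=1)
    points_per_cluster_mean: float = Field(30.0, gt=0)
    cluster_sigma_nm: float = Field(40.0, gt=0)
    nucleus_radius_nm: float = Field(5000.0, gt=0)
    alu_noise_fraction: float = Field(0.05, ge=0, lt=1)

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        if v not in ("stack", "nucleus", "genome", "doses"):
            raise ValueError("kind must be stack, nucleus, genome or doses")
        return v


class PipelineConfig(_Block):
    """Umbrella configuration binding all stages of the analysis."""

    stages: list[str] = Field(default_factory=lambda: ["simulate", "cluster", "shells"])
    seed: int = 0
    out_dir: str = "comboloc_out"
    localizer: LocalizerConfig = Field(default_factory=LocalizerConfig)
    renderer: RendererConfig = Field(default_factory=RendererConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    shells: ShellsConfig = Field(default_factory=ShellsConfig)
    probe: ProbeConfig = Field(default_factory=ProbeConfig)
    dose: DoseConfig = Field(default_factory=DoseConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    @field_validator("stages")
    @classmethod
    def _stages(cls, v: list[str]) -> list[str]:
        known = {"simulate", "localize", "cluster", "shells", "dose", "probe"}
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        return v


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
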