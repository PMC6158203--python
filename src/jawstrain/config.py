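"""Run configuration: schema-validated, unknown keys rejected.

Every pipeline run is fully described by one :class:`PipelineConfig`; the
resolved config is written alongside the outputs so any run directory can be
reproduced bit-for-bit from its own record.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    background_mean: float = 30.0
    foreground_mean: float = 200.0
    sd: float = Field(10.0, ge=0)


class PipelineConfig(BaseModel):
    """Parameters of one end-to-end run (generate -> segment -> solve)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    shape_preset: str = "wt"
    material_preset: str = "wt"
    sigma: float = Field(1.0, ge=0, description="binary smoothing sigma, voxels")
    split_distance: float | None = Field(
        None, ge=0, description="near-joint split distance d, um (default 15% of element length)"
    )
    nu: float = Field(0.3, ge=0, lt=0.5, description="Poisson ratio for AFM conversion")
    min_size: int = Field(5, ge=1, description="protrusion size floor, voxels")
    muscle_scale: float = Field(1.0, ge=0)
    n_exostoses: int = Field(0, ge=0)
    exostosis_radius: float = Field(2.0, gt=0)
    steps: tuple[str, ...] = ("closure", "opening")
    noise: NoiseConfig = NoiseConfig()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML run config (unknown keys are rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
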