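"""Run configuration: every tunable of every stage in one validated object.

Defaults follow the emulated study where it states a value: 2 mm voxels,
TR 3.6 s, 8 mm (4-voxel) searchlight admitted when >50% of its voxels are
grey matter, 80/20 splits repeated 100 times, 100 label shuffles for the
empirical chance level, FDR q = 0.01, clusters of >20 voxels, group
coincidence at 4 of 5 subjects.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .synth import REGION_KINDS

__all__ = ["RegionConfig", "RunConfig"]


class RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str
    centre: tuple[int, int, int]
    radius_voxels: int = Field(ge=1)
    effect_amplitude: float

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in REGION_KINDS:
            raise ValueError(f"kind must be one of {REGION_KINDS}")
        return v


class RunConfig(BaseModel):
    """Lossless, strict (unknown keys rejected) pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    # simulation
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    fill_fraction: float = Field(default=0.4, gt=0.0, le=1.0)
    n_subjects: int = Field(default=5, ge=1)
    n_blocks: int = Field(default=20, ge=1)
    noise_sd: float = Field(default=1.0, ge=0.0)
    regions: list[RegionConfig] = Field(default_factory=list)
    simulate_bold: bool = False
    tr_s: float = Field(default=3.6, gt=0.0)
    stim_duration_s: float = Field(default=0.5, gt=0.0)
    smooth_noise_fwhm_mm: float = Field(default=0.0, ge=0.0)

    # searchlight geometry
    radius_voxels: int = Field(default=4, ge=0)
    min_inmask_fraction: float = Field(default=0.5, ge=0.0, le=1.0)

    # decoding
    schemes: list[str] = Field(
        default_factory=lambda: ["face", "voice", "face_to_voice", "voice_to_face"]
    )
    train_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    n_repeats: int = Field(default=100, ge=1)
    n_shuffles: int = Field(default=100, ge=1)
    svm_C: float = Field(default=1.0, gt=0.0)
    standardize_features: bool = False
    redraw_split_per_shuffle: bool = True

    # inference
    q_fdr: float = Field(default=0.01, gt=0.0, lt=1.0)
    min_cluster_voxels: int = Field(default=20, ge=0)
    connectivity: int = 26
    binomial_n_mode: str = "pool"

    # group level
    min_subjects: int = Field(default=4, ge=1)
    group_cluster_filter: bool = False

    seed: int = 0

    @field_validator("connectivity")
    @classmethod
    def _conn(cls, v: int) -> int:
        if v not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        return v

    @field_validator("binomial_n_mode")
    @classmethod
    def _nmode(cls, v: str) -> str:
        if v not in ("pool", "total", "per_repeat"):
            raise ValueError("binomial_n_mode must be 'pool', 'total' or 'per_repeat'")
        return v

    @field_validator("schemes")
    @classmethod
    def _schemes(cls, v: list[str]) -> list[str]:
        from .decoding import SCHEMES

        bad = [s for s in v if s not in SCHEMES]
        if bad:
            raise ValueError(f"unknown schemes {bad}; expected subset of {list(SCHEMES)}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)
        )
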