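"""Pipeline configuration: schema, validation, stage-seed derivation.

A single YAML document configures every stage.  Validation is strict
(unknown keys rejected, ranges checked, cross-field constraints enforced)
and reports all problems at once.  Stage seeds are derived by hashing
``(master seed, stage name)`` so adding or reordering stages never perturbs
another stage's random stream.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import List

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "validate_config",
    "load_config",
    "stage_seed",
    "demo_config_dict",
]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreferenceConfig(_Strict):
    focal_class: int = Field(5, ge=1, le=8)
    focal_radius: float = Field(1000.0, gt=0)
    strength: float = Field(5.0, ge=0)


class LandscapeConfig(_Strict):
    n_rows: int = Field(512, ge=1)
    n_cols: int = Field(512, ge=1)
    cell_size: float = Field(100.0, gt=0)
    class_mix: List[float] = Field(
        default=[0.20, 0.25, 0.05, 0.15, 0.10, 0.05, 0.08, 0.12],
        min_length=8,
        max_length=8,
    )
    patchiness: float = Field(1500.0, gt=0)
    n_presences: int = Field(100, ge=1)
    min_spacing: float = Field(1000.0, ge=0)
    preference: PreferenceConfig = PreferenceConfig()
    border_band: float = Field(5000.0, ge=0)
    town_count: int = Field(5, ge=0)
    town_radius: float = Field(1500.0, ge=0)
    n_sightings: int = Field(1000, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix must be 8 non-negative proportions summing to 1")
        if self.patchiness < self.cell_size:
            raise ValueError("patchiness must be at least one cell_size")
        if self.border_band >= min(self.n_rows, self.n_cols) * self.cell_size / 2:
            raise ValueError("border_band exhausts the domain")
        return self


class PseudoabsenceConfig(_Strict):
    min_sighting_dist: float = Field(1000.0, ge=0)
    avoid_towns: bool = True
    n_candidates: int = Field(500, ge=1)
    n_draw: int = Field(100, ge=0)
    n_reps: int = Field(10, ge=1)

    @model_validator(mode="after")
    def _check(self):
        if self.n_draw > self.n_candidates:
            raise ValueError("n_draw must not exceed n_candidates")
        return self


class ModelStageConfig(_Strict):
    radii_km: List[float] = Field(
        default=[0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20], min_length=1
    )
    n_models: int = Field(100, ge=1)
    n_trees: int = Field(500, ge=1)
    oob_fraction: float = Field(0.30, gt=0, lt=1)
    sampling: str = Field("subsample70", pattern="^(subsample70|bootstrap)$")

    @model_validator(mode="after")
    def _check(self):
        if any(r <= 0 for r in self.radii_km):
            raise ValueError("radii_km must be positive")
        if len(set(self.radii_km)) != len(self.radii_km):
            raise ValueError("radii_km must be distinct")
        return self


class ScreenConfig(_Strict):
    rings_km: List[List[float]] = Field(default=[[1, 2], [6, 8]])
    deletion_counts: List[int] = Field(default=[1, 5, 10, 25, 50])
    reps_per_k: int = Field(5, ge=1)
    n_models: int = Field(20, ge=1)
    n_trees: int = Field(100, ge=1)

    @model_validator(mode="after")
    def _check(self):
        for ring in self.rings_km:
            if len(ring) != 2 or not 0 <= ring[0] < ring[1]:
                raise ValueError(f"ring {ring} must be [inner_km, outer_km] with inner < outer")
        if any(k < 0 or k > 50 for k in self.deletion_counts):
            raise ValueError("deletion_counts must lie in [0, 50]")
        return self


class StatsConfig(_Strict):
    alpha_normality: float = Field(0.05, gt=0, lt=1)
    nmds_scale_km: float = Field(1.0, gt=0)
    nmds_n_init: int = Field(8, ge=1)


class PipelineConfig(_Strict):
    seed: int = Field(..., ge=0, lt=2**31)
    landscape: LandscapeConfig = LandscapeConfig()
    pseudoabsence: PseudoabsenceConfig = PseudoabsenceConfig()
    model: ModelStageConfig = ModelStageConfig()
    screen: ScreenConfig = ScreenConfig()
    stats: StatsConfig = StatsConfig()


def _format_errors(err: ValidationError) -> list[str]:
    out = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        out.append(f"{loc}: {e['msg']}")
    return out


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; raise ConfigError listing
    every problem at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"YAML parse error: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    return load_config(raw)


def load_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with the
    master seed, kept below 2**31."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (master_seed * 2654435761)) % (2**31)


def demo_config_dict(seed: int = 0) -> dict:
    """Reduced-size demo configuration: small grid and ensembles so the full
    pipeline completes in minutes on one CPU while exercising every stage."""
    return {
        "seed": seed,
        "landscape": {
            "n_rows": 256,
            "n_cols": 256,
            "cell_size": 100.0,
            "patchiness": 1200.0,
            "n_presences": 60,
            "min_spacing": 1000.0,
            "n_sightings": 400,
            "border_band": 2000.0,
            "town_count": 3,
            "town_radius": 1000.0,
            "preference": {"focal_class": 5, "focal_radius": 1000.0, "strength": 5.0},
        },
        "pseudoabsence": {
            "min_sighting_dist": 800.0,
            "n_candidates": 300,
            "n_draw": 60,
            "n_reps": 1,
        },
        "model": {
            "radii_km": [0.5, 1, 2, 3, 4, 5, 6, 8, 10],
            "n_models": 20,
            "n_trees": 100,
        },
        "screen": {
            "rings_km": [[1, 2], [6, 8]],
            "deletion_counts": [1, 5, 10],
            "reps_per_k": 3,
            "n_models": 10,
            "n_trees": 60,
        },
        "stats": {"nmds_scale_km": 1.0},
    }
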