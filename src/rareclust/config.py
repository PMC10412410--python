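"""Structured run configuration, validated en bloc before any compute.

A single YAML file configures every stage; unknown keys are rejected so a
typo never silently falls back to a default.  CLI flags override file
values; the fully materialized config is echoed into each run manifest so
"what ran" is never ambiguous.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessConfig(_Strict):
    scale_factor: float = Field(1e4, gt=0)
    n_hvgs: int = Field(2000, gt=0)
    hvg_method: Literal["vst_like", "dispersion"] = "vst_like"
    n_pcs: int = Field(30, ge=2)
    distance_space: Literal["pca", "hvg_lognorm"] = "pca"


class ClusterConfig(_Strict):
    """Initial (conservative) broad-pass parameters."""

    k: int = Field(20, ge=2)
    r: float = Field(0.3, gt=0)
    algorithm: Literal["leiden", "louvain"] = "leiden"
    prune: float = Field(1.0 / 15.0, ge=0, lt=1)


class ReclusterConfig(_Strict):
    threshold: float = 0.4
    grid_k: list[int] = Field(default_factory=lambda: [10, 20, 30, 50])
    grid_r: list[float] = Field(
        default_factory=lambda: [0.4, 0.6, 0.8, 1.0, 1.2]
    )
    n_hvgs: int = Field(500, gt=0)  # local re-selection size
    n_pcs: int = Field(10, ge=2)  # local embedding dimension
    force_include: list[str] = Field(default_factory=list)
    force_exclude: list[str] = Field(default_factory=list)
    max_depth: int = Field(2, ge=1)
    min_subset: int = Field(50, ge=2)
    min_subcluster: int = Field(5, ge=1)
    accept_min_coef: float = 0.25
    score: Literal["mean", "median"] = "mean"

    @field_validator("grid_k", "grid_r")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("grid must be non-empty")
        if any(x <= 0 for x in v):
            raise ValueError("grid values must be positive")
        return v


class MarkersConfig(_Strict):
    alpha: float = Field(0.05, gt=0, le=1)
    min_lfc: float = 0.25
    pct_cutoff: float = Field(0.10, gt=0, lt=1)
    strict_filter: bool = False


class SilhouetteConfig(_Strict):
    subsample_cap: int = Field(10_000, ge=100)
    min_per_cluster: int = Field(50, ge=1)


class RunConfig(_Strict):
    input: Optional[str] = None
    layout: Literal["auto", "mtx_triplet", "dense_tsv"] = "auto"
    output_dir: str = "rareclust_out"
    seed: int = 0
    verbosity: Literal["quiet", "normal", "verbose"] = "normal"
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    recluster: ReclusterConfig = Field(default_factory=ReclusterConfig)
    markers: MarkersConfig = Field(default_factory=MarkersConfig)
    silhouette: SilhouetteConfig = Field(default_factory=SilhouetteConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # noqa: BLE001 - keep one error type outward
            raise ValidationError(f"invalid config {path}: {exc}") from exc
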