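"""Configuration objects for the scoring rubric and the morphometry engine.

The ordinal rubric has a small set of numeric anchors (basement-membrane
thickness cuts at 100 and 200 nm, reduplication cuts at 2 and 4 layers,
ensheathment cuts at 5 and 7 processes).  Everything the rubric defines only
qualitatively — what counts as an "increased" endothelial area, how large a
small/medium/large tubuloreticular inclusion is — lives here as an explicit,
documented convention so that it can be changed in one place (or in a YAML
file) without touching scoring code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = [
    "ScoringThresholds",
    "ActivationConfig",
    "TriSizeClasses",
    "MorphometryConfig",
    "RubricConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class ScoringThresholds:
    """Numeric cut-points of the five-category capillary rubric.

    Defaults reproduce the published rubric: thickness bands 50–100 / 100–200 /
    200+ nm, reduplication bands 1 / 2–3 / 4+ layers, ensheathment bands
    0–4 / 5–6 / 7+ processes.  Bands are half-open on the right:
    ``score 1 <=> cut_1 <= x < cut_2`` and ``score 2 <=> x >= cut_2``.
    """

    bm_cut_1_nm: float = 100.0
    bm_cut_2_nm: float = 200.0
    layers_cut_1: int = 2
    layers_cut_2: int = 4
    proc_cut_1: int = 5
    proc_cut_2: int = 7

    def __post_init__(self) -> None:
        pairs = [
            ("bm_cut_1_nm", "bm_cut_2_nm"),
            ("layers_cut_1", "layers_cut_2"),
            ("proc_cut_1", "proc_cut_2"),
        ]
        for lo, hi in pairs:
            a, b = getattr(self, lo), getattr(self, hi)
            if not (0 < a < b):
                raise ConfigError(f"require 0 < {lo} < {hi}, got {a} and {b}")


@dataclass(frozen=True)
class ActivationConfig:
    """How a raw endothelial measurement maps to the activation category.

    The rubric defines endothelial activation only qualitatively ("increased
    area and/or organelles"), so the quantitative mapping is a convention:
    the endothelial cross-sectional area is expressed as a ratio to
    ``reference_area_um2`` (a plausible healthy capillary endothelial
    cross-section) and banded at ``mild_ratio`` and ``marked_ratio``; the
    area band combines with the observed organelle prominence by a max rule.
    """

    reference_area_um2: float = 5.0
    mild_ratio: float = 1.5
    marked_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.reference_area_um2 <= 0:
            raise ConfigError("reference_area_um2 must be positive")
        if not (1.0 <= self.mild_ratio < self.marked_ratio):
            raise ConfigError("require 1 <= mild_ratio < marked_ratio")


@dataclass(frozen=True)
class TriSizeClasses:
    """Maximum-diameter conventions for small/medium/large tubuloreticular
    inclusions, in nm.  These are configurable conventions — the rubric names
    the classes but never quantifies them."""

    small_max_nm: float = 300.0
    medium_max_nm: float = 800.0

    def __post_init__(self) -> None:
        if not (0 < self.small_max_nm < self.medium_max_nm):
            raise ConfigError("require 0 < small_max_nm < medium_max_nm")

    def classify(self, diameter_nm: float) -> str:
        if not diameter_nm > 0:
            raise ConfigError(f"TRI diameter must be positive, got {diameter_nm}")
        if diameter_nm < self.small_max_nm:
            return "small"
        if diameter_nm <= self.medium_max_nm:
            return "medium"
        return "large"


@dataclass(frozen=True)
class MorphometryConfig:
    """Geometry-engine settings.

    ``n_rays`` radial rays measure BM thickness (summarised by
    ``thickness_summary``); processes are counted inside a peri-capillary
    annulus of width ``annulus_width_nm`` outside the outermost BM layer, and
    ensheathment prominence is banded on the fraction of the perimeter the
    processes cover.
    """

    n_rays: int = 36
    thickness_summary: str = "median"
    annulus_width_nm: float = 1000.0
    coverage_focal_max: float = 0.25
    coverage_prominent_max: float = 0.75
    pixel_size_nm: float = 7.3

    def __post_init__(self) -> None:
        if self.n_rays < 8:
            raise ConfigError("n_rays must be >= 8")
        if self.thickness_summary not in ("median", "mean", "max"):
            raise ConfigError("thickness_summary must be median, mean or max")
        if self.annulus_width_nm <= 0:
            raise ConfigError("annulus_width_nm must be positive")
        if not (0 < self.coverage_focal_max < self.coverage_prominent_max < 1):
            raise ConfigError("coverage bands must satisfy 0 < focal < prominent < 1")
        if self.pixel_size_nm <= 0:
            raise ConfigError("pixel_size_nm must be positive")


@dataclass(frozen=True)
class RubricConfig:
    """Bundle of all scoring + morphometry settings; the single object read
    from / written to a YAML config file."""

    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)
    activation: ActivationConfig = field(default_factory=ActivationConfig)
    tri_sizes: TriSizeClasses = field(default_factory=TriSizeClasses)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)

    def to_dict(self) -> dict[str, Any]:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "activation": dataclasses.asdict(self.activation),
            "tri_sizes": dataclasses.asdict(self.tri_sizes),
            "morphometry": dataclasses.asdict(self.morphometry),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RubricConfig":
        known = {"thresholds", "activation", "tri_sizes", "morphometry"}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config sections: {sorted(extra)}")
        try:
            return cls(
                thresholds=ScoringThresholds(**data.get("thresholds", {})),
                activation=ActivationConfig(**data.get("activation", {})),
                tri_sizes=TriSizeClasses(**data.get("tri_sizes", {})),
                morphometry=MorphometryConfig(**data.get("morphometry", {})),
            )
        except TypeError as exc:  # unknown key inside a section
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None) -> RubricConfig:
    """Load a :class:`RubricConfig` from YAML; ``None`` returns the defaults."""
    if path is None:
        return RubricConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return RubricConfig.from_dict(data)


def save_config(config: RubricConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RubricConfig | Mapping[str, Any]) -> str:
    """Stable sha256 over the canonical JSON form, for run manifests."""
    data = config.to_dict() if isinstance(config, RubricConfig) else dict(config)
    blob = json.dumps(data, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()
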