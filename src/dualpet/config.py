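"""Pipeline configuration: YAML round-trip with explicit validation.

A :class:`PipelineConfig` fully determines a run — grid, cohort design,
pathology calibration, FDR level, optional pre-statistics smoothing and the
master seed — so re-running with an identical config reproduces every
numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import GridSpec
from .phantom import (
    DEFAULT_GRID,
    BiomarkerSpec,
    CohortDesign,
    PathologyParams,
)

__all__ = ["PipelineConfig", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    grid: GridSpec = DEFAULT_GRID
    design: CohortDesign = field(default_factory=CohortDesign)
    params: PathologyParams = field(default_factory=PathologyParams)
    q: float = 0.05  # FDR level of the voxel-wise stage
    fwhm_mm: float = 0.0  # optional pre-statistics smoothing (0 = off)
    target_voi: str = "target_forebrain"
    seed: int = 0  # master seed; overrides design.seed

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {
            "grid": {"shape": list(self.grid.shape), "voxel_size": list(self.grid.voxel_size)},
            "design": {
                "age_groups": list(self.design.age_groups),
                "n_per_group": self.design.n_per_group,
                "genotypes": list(self.design.genotypes),
                "tracers": list(self.design.tracers),
            },
            "params": _params_to_dict(self.params),
            "q": self.q,
            "fwhm_mm": self.fwhm_mm,
            "target_voi": self.target_voi,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - {"grid", "design", "params", "q", "fwhm_mm", "target_voi", "seed"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        if "grid" in d:
            g = d["grid"]
            kwargs["grid"] = GridSpec(tuple(g["shape"]), tuple(g["voxel_size"]))
        if "design" in d:
            des = dict(d["design"])
            des.pop("seed", None)
            for key in ("age_groups", "genotypes", "tracers"):
                if key in des:
                    des[key] = tuple(des[key])
            kwargs["design"] = CohortDesign(**des)
        if "params" in d:
            kwargs["params"] = _params_from_dict(d["params"])
        for key in ("q", "fwhm_mm", "target_voi", "seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _params_to_dict(p: PathologyParams) -> dict[str, Any]:
    d = dataclasses.asdict(p)
    d["amyloid_onset_months"] = dict(p.amyloid_onset_months)
    d["amyloid_region_amplitude"] = dict(p.amyloid_region_amplitude)
    d["biomarkers"] = {
        name: dataclasses.asdict(spec) for name, spec in p.biomarkers.items()
    }
    return d


def _params_from_dict(d: dict[str, Any]) -> PathologyParams:
    d = dict(d)
    if "biomarkers" in d:
        d["biomarkers"] = {
            name: spec if isinstance(spec, BiomarkerSpec) else BiomarkerSpec(**spec)
            for name, spec in d["biomarkers"].items()
        }
    valid = {f.name for f in dataclasses.fields(PathologyParams)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown pathology parameters: {sorted(unknown)}")
    return PathologyParams(**d)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
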