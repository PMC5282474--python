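"""Core containers for volumetric PET data.

The pipeline operates on static, reference-scaled uptake images that are
assumed to be co-registered onto one common grid together with an integer
labelled region atlas. Registration itself is out of scope: every volume
entering the analysis must already live on the same :class:`GridSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "ImageVolume",
    "RegionAtlas",
    "SizingError",
    "DesignError",
    "load_volume",
    "save_volume",
    "load_atlas",
    "save_atlas",
]


class SizingError(ValueError):
    """A region does not fit on the requested grid."""


class DesignError(ValueError):
    """A cohort design violates the requirements of the downstream statistics."""


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid: array shape plus physical voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass
class ImageVolume:
    """A 3D scalar uptake field on a :class:`GridSpec` (arbitrary units)."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    def same_grid(self, other: "ImageVolume | RegionAtlas") -> bool:
        return self.grid == other.grid


@dataclass
class RegionAtlas:
    """Integer-labelled region volume plus named volumes of interest.

    ``labels`` uses 0 for background (outside the brain); the brain mask is
    ``labels > 0``.  ``voi_defs`` maps a VOI name to the set of labels it
    comprises, and must contain at minimum the forebrain target and the two
    tracer-specific white-matter reference regions.
    """

    labels: np.ndarray
    grid: GridSpec
    region_names: Mapping[int, str]
    voi_defs: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label volume shape does not match grid")
        present = set(np.unique(self.labels)) - {0}
        for name, labs in self.voi_defs.items():
            missing = set(labs) - present
            if missing:
                raise ValueError(f"VOI {name!r} references absent labels {sorted(missing)}")
        if not present:
            raise ValueError("atlas has an empty brain mask")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def voi_mask(self, name: str) -> np.ndarray:
        try:
            labs = self.voi_defs[name]
        except KeyError:
            raise KeyError(f"unknown VOI {name!r}; known: {sorted(self.voi_defs)}") from None
        return np.isin(self.labels, list(labs))

    def voi_volume_mm3(self, name: str) -> float:
        return float(self.voi_mask(name).sum()) * self.grid.voxel_volume

    def label_of(self, region_name: str) -> int:
        for lab, nm in self.region_names.items():
            if nm == region_name:
                return lab
        raise KeyError(f"unknown region {region_name!r}")


def _grid_from_nifti(img: nib.Nifti1Image) -> GridSpec:
    zooms = img.header.get_zooms()[:3]
    return GridSpec(tuple(img.shape[:3]), tuple(float(z) for z in zooms))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=float), _grid_from_nifti(img))


def save_volume(vol: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine), str(path))
    return path


def save_atlas(atlas: RegionAtlas, nifti_path: str | Path, json_path: str | Path) -> None:
    """Write the label volume as NIfTI and the name/VOI maps as JSON."""
    nifti_path = Path(nifti_path)
    nifti_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine), str(nifti_path)
    )
    meta = {
        "region_names": {str(k): v for k, v in atlas.region_names.items()},
        "voi_defs": {k: sorted(v) for k, v in atlas.voi_defs.items()},
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_atlas(nifti_path: str | Path, json_path: str | Path) -> RegionAtlas:
    img = nib.load(str(nifti_path))
    meta = json.loads(Path(json_path).read_text())
    return RegionAtlas(
        labels=np.asarray(img.dataobj).astype(int),
        grid=_grid_from_nifti(img),
        region_names={int(k): v for k, v in meta["region_names"].items()},
        voi_defs={k: frozenset(v) for k, v in meta["voi_defs"].items()},
    )
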