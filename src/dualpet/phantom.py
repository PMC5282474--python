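"""Synthetic dual-tracer mouse-brain phantom cohorts.

This module generates everything the downstream analysis consumes: a
parametric region atlas, reference-scaled uptake images for a TSPO
(neuroinflammation) tracer and an amyloid tracer, and terminal fluid
biomarkers (sTREM2, total Abeta, proinflammatory cytokines) coupled to each
subject's own imaging burden.

The data-generating model emulates a cross-sectional transgenic-vs-wild-type
amyloidosis study at four ages:

* **Amyloid burden** follows truncated logistic growth per region — exactly
  zero at or before a region-specific onset age, saturating at a
  region-specific amplitude.  Wild-type animals carry no amyloid.
* **Inflammation burden** is a spatially diffuse component (a Gaussian-blurred
  cortical/cerebellar indicator, widespread from an early onset age) plus a
  plaque-associated component proportional to the subject's local amyloid
  burden, plus a small linear aging drift present in both genotypes.
* **Reference regions** (white-matter VOIs) are pathology-free by
  construction, so reference scaling is well defined.
* **Biomarkers** are log-linear in the subject's forebrain burden with
  multiplicative lognormal noise, so they are positive, monotone in burden
  when noise-free, and have an analytically known burden correlation.

Each subject owns an independent random substream derived from the master
seed and the subject's design cell, so cohorts are bit-reproducible and
insensitive to iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import DesignError, GridSpec, ImageVolume, RegionAtlas, SizingError, save_volume

__all__ = [
    "DEFAULT_GRID",
    "CohortDesign",
    "BiomarkerSpec",
    "PathologyParams",
    "PhantomModel",
    "CohortData",
    "build_atlas",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "implied_log_correlation",
]

#: 0.4 mm isotropic default grid; finer than a typical small-animal PET
#: reconstruction so that voxel-wise statistics have non-trivial support.
DEFAULT_GRID = GridSpec((36, 50, 30), (0.4, 0.4, 0.4))

GENOTYPES = ("TG", "WT")
TRACERS = ("tspo", "amyloid")

# Region boxes in mm: name -> (origin_xyz, size_xyz). Laid out along the
# anterior-posterior (y) axis inside a 12 x 18 x 10 mm brain. Sizes are
# chosen so that on the default grid the forebrain target VOI comes to
# ~156 mm^3 and the two white-matter reference VOIs to ~29 and ~67 mm^3.
_REGION_BOXES_MM: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "frontal_cortex": ((5.2, 0.8, 6.8), (4.0, 7.6, 2.0)),
    "parietal_cortex": ((5.2, 8.8, 6.8), (4.0, 6.4, 2.0)),
    "hippocampus": ((5.2, 9.6, 4.4), (4.0, 3.2, 2.0)),
    "thalamus": ((5.6, 6.4, 4.0), (3.2, 2.4, 2.4)),
    "piriform_entorhinal_cortex": ((1.6, 7.2, 4.8), (2.4, 4.0, 2.0)),
    "cerebellum": ((4.8, 16.0, 4.8), (4.8, 2.0, 4.0)),
    "brainstem": ((5.6, 15.2, 0.0), (3.2, 4.0, 2.0)),
    "wm_cerebellar_brainstem": ((9.6, 16.0, 3.2), (3.2, 3.2, 2.8)),
    "wm_subcortical": ((5.2, 12.0, 2.0), (4.4, 7.6, 2.0)),
}

_FILLER_REGION = "other_brain"

#: Configured physical volumes (mm^3) of the special-purpose VOIs.
VOI_TARGET_VOLUMES_MM3 = {
    "ref_wm_tspo": 29.0,
    "ref_wm_amyloid": 67.0,
    "target_forebrain": 156.0,
}

_FOREBRAIN_REGIONS = ("frontal_cortex", "parietal_cortex", "hippocampus", "thalamus")
_INFLAMMATION_REGIONS = (
    "frontal_cortex",
    "parietal_cortex",
    "piriform_entorhinal_cortex",
    "hippocampus",
    "thalamus",
    "cerebellum",
)

# Brain envelope: superellipsoid |x/a|^4 + |y/b|^4 + |z/c|^4 <= 1, which
# fills the bounding box better than an ellipsoid.
_BRAIN_CENTER_MM = (7.2, 10.0, 6.0)
_BRAIN_SEMIAXES_MM = (6.0, 9.0, 5.0)
_BRAIN_EXPONENT = 4.0


def build_atlas(grid: GridSpec = DEFAULT_GRID) -> RegionAtlas:
    """Construct the parametric region atlas on ``grid``.

    Regions are axis-aligned boxes defined in mm and snapped to the voxel
    grid; the brain mask is the union of a smooth brain envelope and all
    region boxes, with non-region brain voxels labelled ``other_brain``.

    Raises
    ------
    SizingError
        If any region collapses to zero voxels or falls outside the grid.
    """
    labels = np.zeros(grid.shape, dtype=np.int16)
    region_names: dict[int, str] = {}
    name_to_label: dict[str, int] = {}

    for lab, (name, (origin, size)) in enumerate(_REGION_BOXES_MM.items(), start=1):
        sl = []
        for ax in range(3):
            lo = int(round(origin[ax] / grid.voxel_size[ax]))
            hi = int(round((origin[ax] + size[ax]) / grid.voxel_size[ax]))
            if lo < 0 or hi > grid.shape[ax] or hi <= lo:
                raise SizingError(
                    f"region {name!r} does not fit on grid {grid.shape} "
                    f"(axis {ax}: voxels {lo}:{hi})"
                )
            sl.append(slice(lo, hi))
        box = labels[tuple(sl)]
        if np.any(box != 0):
            raise SizingError(f"region {name!r} overlaps a previously placed region")
        labels[tuple(sl)] = lab
        region_names[lab] = name
        name_to_label[name] = lab

    # Smooth brain envelope for the filler tissue.
    coords = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(grid.shape, grid.voxel_size)], indexing="ij"
    )
    u = sum(
        np.abs((c - c0) / a) ** _BRAIN_EXPONENT
        for c, c0, a in zip(coords, _BRAIN_CENTER_MM, _BRAIN_SEMIAXES_MM)
    )
    envelope = u <= 1.0
    filler_label = len(_REGION_BOXES_MM) + 1
    labels[envelope & (labels == 0)] = filler_label
    region_names[filler_label] = _FILLER_REGION
    name_to_label[_FILLER_REGION] = filler_label

    voi_defs = {name: frozenset({lab}) for name, lab in name_to_label.items()}
    voi_defs["target_forebrain"] = frozenset(name_to_label[r] for r in _FOREBRAIN_REGIONS)
    voi_defs["ref_wm_tspo"] = frozenset({name_to_label["wm_cerebellar_brainstem"]})
    voi_defs["ref_wm_amyloid"] = frozenset({name_to_label["wm_subcortical"]})

    atlas = RegionAtlas(labels=labels, grid=grid, region_names=region_names, voi_defs=voi_defs)
    for voi, target in VOI_TARGET_VOLUMES_MM3.items():
        vol = atlas.voi_volume_mm3(voi)
        if abs(vol - target) > 0.10 * target:
            raise SizingError(
                f"VOI {voi!r} realises {vol:.1f} mm^3 on this grid, "
                f"more than 10% from its configured {target:.0f} mm^3"
            )
    return atlas


@dataclass(frozen=True)
class CohortDesign:
    """Cross-sectional design: equal-sized TG/WT groups at several ages."""

    age_groups: tuple[float, ...] = (5.0, 8.0, 13.0, 16.0)
    n_per_group: int = 8
    seed: int = 0
    genotypes: tuple[str, ...] = GENOTYPES
    tracers: tuple[str, ...] = TRACERS

    def __post_init__(self) -> None:
        ages = tuple(float(a) for a in self.age_groups)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise DesignError("age groups must be strictly increasing")
        if self.n_per_group < 2:
            raise DesignError(
                "n_per_group must be >= 2: the voxel-wise t-test is undefined otherwise"
            )
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise DesignError(f"unknown genotype {g!r}")
        for t in self.tracers:
            if t not in TRACERS:
                raise DesignError(f"unknown tracer {t!r}")
        object.__setattr__(self, "age_groups", ages)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Log-linear coupling of one terminal biomarker to imaging burden.

    ``log Y = log(baseline) + slope * burden + noise`` with lognormal
    multiplicative noise of coefficient of variation ``noise_cv`` (mean 1).
    ``pathology`` selects which forebrain burden drives the biomarker.
    """

    baseline: float
    slope: float
    noise_cv: float
    pathology: str  # "inflammation" or "amyloid"

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.slope < 0 or self.noise_cv < 0:
            raise ValueError("biomarker baseline must be > 0; slope and noise_cv >= 0")
        if self.pathology not in ("inflammation", "amyloid"):
            raise ValueError(f"unknown pathology driver {self.pathology!r}")

    @property
    def log_noise_sd(self) -> float:
        return math.sqrt(math.log1p(self.noise_cv**2))


def _default_biomarkers() -> dict[str, BiomarkerSpec]:
    return {
        "sTREM2": BiomarkerSpec(800.0, 1.3, 0.05, "inflammation"),
        "total_Abeta": BiomarkerSpec(40.0, 1.3, 0.15, "amyloid"),
        "IL_1b": BiomarkerSpec(4.0, 0.7, 0.25, "inflammation"),
        "IL_6": BiomarkerSpec(6.0, 0.6, 0.25, "inflammation"),
        "KC_GRO": BiomarkerSpec(20.0, 0.6, 0.25, "inflammation"),
    }


def _default_amyloid_onsets() -> dict[str, float]:
    # Months. Frontal cortex and thalamus lead; cerebellum, brainstem and the
    # white-matter references never develop amyloid.
    return {
        "frontal_cortex": 6.0,
        "thalamus": 6.5,
        "parietal_cortex": 9.5,
        "hippocampus": 11.0,
        "piriform_entorhinal_cortex": 12.0,
        _FILLER_REGION: 12.5,
    }


def _default_amyloid_amplitudes() -> dict[str, float]:
    return {
        "frontal_cortex": 1.0,
        "thalamus": 0.85,
        "parietal_cortex": 0.9,
        "hippocampus": 0.8,
        "piriform_entorhinal_cortex": 0.7,
        _FILLER_REGION: 0.15,
    }


@dataclass(frozen=True)
class PathologyParams:
    """Calibration of the phantom's pathology and biomarker model.

    Units: ages and onsets in months, spatial extents in mm, amplitudes and
    burdens dimensionless (burden ~1 at saturation in the leading region),
    image noise in reference-scaled uptake units.
    """

    amyloid_onset_months: Mapping[str, float] = field(default_factory=_default_amyloid_onsets)
    amyloid_region_amplitude: Mapping[str, float] = field(
        default_factory=_default_amyloid_amplitudes
    )
    amyloid_growth_rate: float = 0.25  # per month
    k_amyloid: float = 0.35  # fractional uptake increase at unit amyloid burden
    k_inflammation: float = 0.25
    inflammation_onset_months: float = 2.0
    inflammation_growth_rate: float = 0.15
    diffuse_extent_mm: float = 2.0  # FWHM of the diffuse inflammation field
    plaque_inflammation_weight: float = 0.25
    wt_drift_per_month: float = 0.013  # linear aging drift of inflammation burden
    noise_sd: float = 0.04
    subject_cv_inflammation: float = 0.08
    subject_cv_amyloid: float = 0.25
    biomarkers: Mapping[str, BiomarkerSpec] = field(default_factory=_default_biomarkers)

    def __post_init__(self) -> None:
        nonneg = {
            "amyloid_growth_rate": self.amyloid_growth_rate,
            "k_amyloid": self.k_amyloid,
            "k_inflammation": self.k_inflammation,
            "inflammation_growth_rate": self.inflammation_growth_rate,
            "diffuse_extent_mm": self.diffuse_extent_mm,
            "plaque_inflammation_weight": self.plaque_inflammation_weight,
            "wt_drift_per_month": self.wt_drift_per_month,
            "noise_sd": self.noise_sd,
            "subject_cv_inflammation": self.subject_cv_inflammation,
            "subject_cv_amyloid": self.subject_cv_amyloid,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, amp in self.amyloid_region_amplitude.items():
            if amp < 0:
                raise ValueError(f"amyloid amplitude for {name!r} must be >= 0")

    def null(self) -> "PathologyParams":
        """A copy with all transgenic pathology amplitudes set to zero.

        TG and WT cohorts generated under the result are exchangeable: only
        the shared aging drift and noise remain.
        """
        return replace(
            self,
            amyloid_region_amplitude={k: 0.0 for k in self.amyloid_region_amplitude},
            inflammation_growth_rate=0.0,
        )


def _growth(age: float, onset: float | None, rate: float) -> float:
    """Truncated logistic growth: 0 at/before onset, -> 1 as age grows."""
    if onset is None:
        return 0.0
    return max(0.0, math.tanh(rate * (age - onset)))


class PhantomModel:
    """Precomputed spatial fields for one (atlas, params) pair.

    Burden maps are deterministic given genotype, age and the subject's
    severity factors; images add white Gaussian noise on top.
    """

    def __init__(self, atlas: RegionAtlas, params: PathologyParams = PathologyParams()):
        self.atlas = atlas
        self.params = params
        self.brain = atlas.brain_mask
        # Reference VOIs are pathology-free so that reference scaling is exact.
        self._pathology_ok = self.brain & ~atlas.voi_mask("ref_wm_tspo") & ~atlas.voi_mask(
            "ref_wm_amyloid"
        )
        self._label_lut_size = int(atlas.labels.max()) + 1
        self._amp_lut = np.zeros(self._label_lut_size)
        self._onset_by_label: list[float | None] = [None] * self._label_lut_size
        for lab, name in atlas.region_names.items():
            self._amp_lut[lab] = params.amyloid_region_amplitude.get(name, 0.0)
            self._onset_by_label[lab] = params.amyloid_onset_months.get(name)
        self.diffuse_field = self._make_diffuse_field()

    def _make_diffuse_field(self) -> np.ndarray:
        atlas, params = self.atlas, self.params
        indic = np.isin(
            atlas.labels, [atlas.label_of(r) for r in _INFLAMMATION_REGIONS]
        ).astype(float)
        if params.diffuse_extent_mm > 0:
            sigma_vox = [
                params.diffuse_extent_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v
                for v in atlas.grid.voxel_size
            ]
            indic = gaussian_filter(indic, sigma=sigma_vox, mode="constant")
        if indic.max() > 0:
            indic /= indic.max()
        indic[~self._pathology_ok] = 0.0
        return indic

    def amyloid_burden(self, genotype: str, age: float, subject_scale: float = 1.0) -> np.ndarray:
        _check_genotype(genotype)
        if genotype == "WT":
            return np.zeros(self.atlas.grid.shape)
        p = self.params
        per_label = np.array(
            [
                self._amp_lut[lab] * _growth(age, self._onset_by_label[lab], p.amyloid_growth_rate)
                for lab in range(self._label_lut_size)
            ]
        )
        burden = subject_scale * per_label[self.atlas.labels]
        burden[~self._pathology_ok] = 0.0
        return burden

    def inflammation_burden(
        self,
        genotype: str,
        age: float,
        subject_scale: float = 1.0,
        amyloid_map: np.ndarray | None = None,
    ) -> np.ndarray:
        _check_genotype(genotype)
        p = self.params
        burden = np.zeros(self.atlas.grid.shape)
        burden[self._pathology_ok] = p.wt_drift_per_month * age
        if genotype == "TG":
            s = _growth(age, p.inflammation_onset_months, p.inflammation_growth_rate)
            if amyloid_map is None:
                amyloid_map = self.amyloid_burden(genotype, age, subject_scale=subject_scale)
            burden += subject_scale * s * (
                self.diffuse_field + p.plaque_inflammation_weight * amyloid_map
            )
        return burden

    def simulate_image(
        self,
        genotype: str,
        age: float,
        tracer: str,
        rng: np.random.Generator,
        subject_scale_inflammation: float = 1.0,
        subject_scale_amyloid: float = 1.0,
    ) -> ImageVolume:
        _check_tracer(tracer)
        p = self.params
        if tracer == "amyloid":
            field = p.k_amyloid * self.amyloid_burden(genotype, age, subject_scale_amyloid)
        else:
            amy = self.amyloid_burden(genotype, age, subject_scale_amyloid)
            field = p.k_inflammation * self.inflammation_burden(
                genotype, age, subject_scale_inflammation, amyloid_map=amy
            )
        data = 1.0 + field
        if p.noise_sd > 0:
            data = data + p.noise_sd * rng.standard_normal(self.atlas.grid.shape)
        return ImageVolume(data, self.atlas.grid)


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


def _check_tracer(tracer: str) -> None:
    if tracer not in TRACERS:
        raise ValueError(f"unknown tracer {tracer!r}; expected one of {TRACERS}")


def simulate_subject(
    atlas: RegionAtlas,
    genotype: str,
    age: float,
    params: PathologyParams,
    tracer: str,
    rng: np.random.Generator,
    subject_scale_inflammation: float = 1.0,
    subject_scale_amyloid: float = 1.0,
) -> ImageVolume:
    """Simulate one reference-scaled uptake image for one subject.

    Identical ``rng`` state yields a bit-identical image.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    model = PhantomModel(atlas, params)
    return model.simulate_image(
        genotype, age, tracer, rng, subject_scale_inflammation, subject_scale_amyloid
    )


@dataclass
class CohortData:
    """In-memory result of a cohort simulation."""

    manifest: pd.DataFrame  # subject_id, genotype, age_months, tracer, path, seed
    images: dict[tuple[str, str], ImageVolume]  # (subject_id, tracer) -> image
    biomarkers: pd.DataFrame  # one row per subject
    atlas: RegionAtlas
    design: CohortDesign
    params: PathologyParams


def _subject_stream(seed: int, genotype: str, age: float, rep: int) -> np.random.SeedSequence:
    # Keyed on the design cell, not the iteration order.
    return np.random.SeedSequence(
        [int(seed), GENOTYPES.index(genotype), int(round(age * 10)), int(rep)]
    )


def simulate_cohort(
    design: CohortDesign,
    params: PathologyParams = PathologyParams(),
    atlas: RegionAtlas | None = None,
) -> CohortData:
    """Simulate the full cross-sectional cohort: images and terminal biomarkers.

    One image per subject per tracer, and one biomarker row per subject.
    Biomarkers are monotone (log-linear) functions of the subject's own
    noiseless forebrain burden with multiplicative lognormal noise.
    """
    if atlas is None:
        atlas = build_atlas(DEFAULT_GRID)
    model = PhantomModel(atlas, params)
    fb = atlas.voi_mask("target_forebrain")

    manifest_rows = []
    bm_rows = []
    images: dict[tuple[str, str], ImageVolume] = {}
    for genotype in design.genotypes:
        for age in design.age_groups:
            for rep in range(design.n_per_group):
                sid = f"{genotype}-{age:04.1f}m-{rep + 1:02d}"
                ss = _subject_stream(design.seed, genotype, age, rep)
                severity_rng, tspo_rng, amy_rng, bm_rng = [
                    np.random.default_rng(c) for c in ss.spawn(4)
                ]
                # Independent per-subject severity factors (mean 1) for the
                # two pathologies; amyloid load varies more between animals.
                z_i, z_a = severity_rng.standard_normal(2)
                ci, ca = params.subject_cv_inflammation, params.subject_cv_amyloid
                u_i = math.exp(ci * z_i - ci**2 / 2.0)
                u_a = math.exp(ca * z_a - ca**2 / 2.0)

                amy_map = model.amyloid_burden(genotype, age, u_a)
                inf_map = model.inflammation_burden(genotype, age, u_i, amyloid_map=amy_map)
                for tracer, rng in (("tspo", tspo_rng), ("amyloid", amy_rng)):
                    if tracer not in design.tracers:
                        continue
                    images[(sid, tracer)] = model.simulate_image(
                        genotype, age, tracer, rng, u_i, u_a
                    )
                    manifest_rows.append(
                        {
                            "subject_id": sid,
                            "genotype": genotype,
                            "age_months": age,
                            "tracer": tracer,
                            "path": "",
                            "seed": design.seed,
                        }
                    )

                burden = {
                    "inflammation": float(inf_map[fb].mean()),
                    "amyloid": float(amy_map[fb].mean()),
                }
                row = {
                    "subject_id": sid,
                    "genotype": genotype,
                    "age_months": age,
                    "inflammation_burden": burden["inflammation"],
                    "amyloid_burden": burden["amyloid"],
                }
                for name, spec in params.biomarkers.items():
                    sigma = spec.log_noise_sd
                    eps = bm_rng.standard_normal()
                    row[name] = spec.baseline * math.exp(
                        spec.slope * burden[spec.pathology] + sigma * eps - sigma**2 / 2.0
                    )
                bm_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    biomarkers = pd.DataFrame(bm_rows)
    return CohortData(manifest, images, biomarkers, atlas, design, params)


def write_cohort(cohort: CohortData, outdir: str | Path) -> Path:
    """Persist a cohort: NIfTI images, manifest CSV and biomarker CSV."""
    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for _, row in cohort.manifest.iterrows():
        fname = f"{row.subject_id}_{row.tracer}.nii.gz"
        save_volume(cohort.images[(row.subject_id, row.tracer)], img_dir / fname)
        paths.append(str(Path("images") / fname))
    cohort.manifest["path"] = paths
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.biomarkers.to_csv(outdir / "biomarkers.csv", index=False)
    return outdir


def implied_log_correlation(burdens: np.ndarray, spec: BiomarkerSpec) -> float:
    """Model-implied Pearson correlation between log-biomarker and burden.

    Under the generator, ``log Y = const + slope * B + sigma * eps`` with
    independent Gaussian noise, so given the realized burden spread ``s_B``
    the population correlation is ``slope * s_B / sqrt(slope^2 s_B^2 + sigma^2)``.
    """
    s_b = float(np.std(np.asarray(burdens, dtype=float), ddof=1))
    sigma = spec.log_noise_sd
    denom = math.sqrt((spec.slope * s_b) ** 2 + sigma**2)
    if denom == 0.0:
        raise ValueError("degenerate: zero burden spread and zero noise")
    return spec.slope * s_b / denom
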