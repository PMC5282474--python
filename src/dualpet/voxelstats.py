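"""Voxel-wise two-group statistics with FDR thresholding.

Implements the statistical-parametric-mapping style contrast used for
whole-brain TG-vs-WT comparisons: a pooled-variance two-sample Student t per
voxel (one-sided, elevation in TG), Benjamini-Hochberg FDR correction over
all brain-mask voxels, and conversion of the rejection set to an equivalent
T-score threshold used for binarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import DesignError, ImageVolume

__all__ = [
    "TScoreMap",
    "BinaryMap",
    "voxelwise_ttest",
    "benjamini_hochberg",
    "fdr_binarize",
    "smooth_volume",
]


@dataclass
class TScoreMap:
    """Per-voxel two-sample T statistics with one-sided p-values.

    Voxels outside ``mask`` carry NaN. ``df = n1 + n2 - 2``. Voxels with
    zero pooled variance are assigned t = 0, p = 1 (counted in
    ``n_degenerate``).
    """

    t: np.ndarray
    p_one_sided: np.ndarray
    df: int
    mask: np.ndarray
    tracer: str | None = None
    age_months: float | None = None
    n_degenerate: int = 0


@dataclass
class BinaryMap:
    """FDR-thresholded significance map for one tracer and age group."""

    elevated: np.ndarray
    t_threshold: float
    q: float
    n_significant: int
    mask: np.ndarray
    tracer: str | None = None
    age_months: float | None = None


def voxelwise_ttest(
    tg_images: list[ImageVolume],
    wt_images: list[ImageVolume],
    brain_mask: np.ndarray,
    tracer: str | None = None,
    age_months: float | None = None,
) -> TScoreMap:
    """Pooled-variance Student t (TG minus WT) at every brain-mask voxel.

    Equal group sizes are required, mirroring the design constraint of the
    mapping framework this reproduces. The one-sided p tests elevation in
    the transgenic group.
    """
    n1, n2 = len(tg_images), len(wt_images)
    if n1 != n2:
        raise DesignError(f"equal group sizes required, got TG={n1}, WT={n2}")
    if n1 < 2:
        raise DesignError("need at least 2 subjects per group")
    grid = tg_images[0].grid
    for img in (*tg_images, *wt_images):
        if img.grid != grid:
            raise ValueError("all images must share one grid")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != grid.shape:
        raise ValueError("brain mask is not on the image grid")

    tg = np.stack([im.data[brain_mask] for im in tg_images])
    wt = np.stack([im.data[brain_mask] for im in wt_images])
    df = n1 + n2 - 2
    diff = tg.mean(axis=0) - wt.mean(axis=0)
    ss = tg.var(axis=0, ddof=1) * (n1 - 1) + wt.var(axis=0, ddof=1) * (n2 - 1)
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))

    degenerate = se == 0
    t_masked = np.zeros(diff.shape)
    np.divide(diff, se, out=t_masked, where=~degenerate)
    p_masked = stats.t.sf(t_masked, df)
    t_masked[degenerate] = 0.0
    p_masked[degenerate] = 1.0

    t = np.full(grid.shape, np.nan)
    p = np.full(grid.shape, np.nan)
    t[brain_mask] = t_masked
    p[brain_mask] = p_masked
    return TScoreMap(
        t=t,
        p_one_sided=p,
        df=df,
        mask=brain_mask,
        tracer=tracer,
        age_months=age_months,
        n_degenerate=int(degenerate.sum()),
    )


def benjamini_hochberg(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection vector at FDR level q.

    All hypotheses with p not exceeding the largest p(i) <= i*q/m are
    rejected, so ties with the critical p-value are rejected together.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= crit)[0]
    if below.size == 0:
        return np.zeros(m, dtype=bool)
    p_star = sorted_p[below[-1]]
    return p <= p_star


def fdr_binarize(tmap: TScoreMap, q: float = 0.05) -> BinaryMap:
    """Binarize a T-score map at the FDR-corrected threshold.

    BH runs over the one-sided p-values of brain-mask voxels only; the
    rejection set is re-expressed as the smallest rejected T-score, which is
    the map's binarization threshold (+inf when nothing survives).
    """
    pv = tmap.p_one_sided[tmap.mask]
    tv = tmap.t[tmap.mask]
    reject = benjamini_hochberg(pv, q)
    if reject.any():
        t_threshold = float(tv[reject].min())
    else:
        t_threshold = math.inf
    elevated = np.zeros(tmap.mask.shape, dtype=bool)
    elevated[tmap.mask] = tv >= t_threshold
    return BinaryMap(
        elevated=elevated,
        t_threshold=t_threshold,
        q=q,
        n_significant=int(elevated.sum()),
        mask=tmap.mask,
        tracer=tmap.tracer,
        age_months=tmap.age_months,
    )


def smooth_volume(image: ImageVolume, fwhm_mm: float) -> ImageVolume:
    """Isotropic Gaussian smoothing with the kernel width given in mm FWHM.

    ``fwhm_mm = 0`` returns the input unchanged; symmetric (mirror) boundary
    handling keeps the total image sum preserved to numerical tolerance.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return image
    sigma = [
        fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v for v in image.grid.voxel_size
    ]
    return ImageVolume(ndimage.gaussian_filter(image.data, sigma=sigma, mode="mirror"), image.grid)
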