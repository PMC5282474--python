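"""VOI-based SUVR endpoints and group-level summaries.

SUVR (standardized uptake value ratio) is the mean uptake in a target VOI
divided by the mean uptake in a tracer-specific white-matter reference VOI
assumed free of pathology. Because it is a ratio of means on the same image,
SUVR is invariant to any global rescaling of the image — that is the point
of reference scaling.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .core import ImageVolume, RegionAtlas

__all__ = [
    "REFERENCE_VOI",
    "voi_mean",
    "compute_suvr",
    "percent_change",
    "summarize_groups",
    "suvr_table",
]

#: Tracer-specific white-matter reference VOI names.
REFERENCE_VOI = {"tspo": "ref_wm_tspo", "amyloid": "ref_wm_amyloid"}


def voi_mean(image: ImageVolume, mask: np.ndarray) -> float:
    """Arithmetic mean of voxel values inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.grid.shape:
        raise ValueError("mask is not defined on the image grid")
    if not mask.any():
        raise ValueError("empty VOI mask")
    return float(image.data[mask].mean())


def compute_suvr(image: ImageVolume, target: np.ndarray, reference: np.ndarray) -> float:
    """SUVR = mean(target) / mean(reference)."""
    ref = voi_mean(image, reference)
    if ref <= 0:
        raise ValueError(f"reference VOI mean is {ref:.4g} <= 0; image looks corrupt")
    return voi_mean(image, target) / ref


def percent_change(mean_later: float, mean_baseline: float) -> float:
    """Percent change of a later group mean relative to a baseline mean."""
    if mean_baseline <= 0:
        raise ValueError("baseline mean must be > 0")
    return 100.0 * (mean_later - mean_baseline) / mean_baseline


def summarize_groups(
    records: pd.DataFrame,
    value_col: str,
    group_cols: tuple[str, ...] = ("genotype", "age_months"),
) -> pd.DataFrame:
    """Per-group n, mean and unbiased (n-1) SD, ordered by the group columns.

    Raises if any group cell is a singleton — an SD is then undefined.
    """
    out = []
    for key, sub in records.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < 2:
            raise ValueError(f"group cell {dict(zip(group_cols, key))} has n < 2")
        vals = sub[value_col].to_numpy(dtype=float)
        row = dict(zip(group_cols, key))
        row.update(
            measure=value_col,
            n=len(vals),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
        )
        out.append(row)
    return pd.DataFrame(out)


def suvr_table(
    manifest: pd.DataFrame,
    atlas: RegionAtlas,
    get_image: Callable[[pd.Series], ImageVolume],
    target_voi: str = "target_forebrain",
) -> pd.DataFrame:
    """One SUVR record per manifest row (subject x tracer).

    ``get_image`` maps a manifest row to its :class:`ImageVolume`; the
    reference VOI is selected per tracer from :data:`REFERENCE_VOI`.
    """
    target = atlas.voi_mask(target_voi)
    refs = {t: atlas.voi_mask(v) for t, v in REFERENCE_VOI.items()}
    rows = []
    for _, row in manifest.iterrows():
        img = get_image(row)
        rows.append(
            {
                "subject_id": row["subject_id"],
                "genotype": row["genotype"],
                "age_months": row["age_months"],
                "tracer": row["tracer"],
                "target_voi": target_voi,
                "suvr": compute_suvr(img, target, refs[row["tracer"]]),
            }
        )
    return pd.DataFrame(rows)
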