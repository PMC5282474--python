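"""Dual-tracer overlap analysis: category maps, occupancy, Dice, transitions.

The two tracers' binarized significance maps are merged into a four-category
code per brain voxel (0 = neither elevated, 1 = TSPO only, 2 = amyloid only,
3 = both), summarized as percentages of the whole brain volume
(%-occupancy), compared via Dice coefficients, and tracked across age
groups as persisting / newly presenting / disappearing volume fractions.

Dice on *non-binarized* T-score maps uses the fuzzy (min-based) extension on
the positive parts of the T-fields, which reduces exactly to binary Dice on
0/1-valued fields while weighting agreement by regional magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .voxelstats import BinaryMap, TScoreMap

__all__ = [
    "CATEGORY_LEGEND",
    "CategoryMap",
    "OccupancyResult",
    "TransitionFlow",
    "combine_categories",
    "occupancy",
    "dice_binary",
    "dice_continuous",
    "transition_flows",
]

log = logging.getLogger(__name__)

CATEGORY_LEGEND = {0: "neither", 1: "tspo_only", 2: "amyloid_only", 3: "both"}


@dataclass
class CategoryMap:
    """Per-voxel overlap code 0-3 within the brain mask (0 outside)."""

    codes: np.ndarray
    mask: np.ndarray
    age_months: float | None = None

    def tracer_elevated(self, tracer: str) -> np.ndarray:
        """Elevation status of one tracer recovered from the codes."""
        if tracer == "tspo":
            return np.isin(self.codes, (1, 3)) & self.mask
        if tracer == "amyloid":
            return np.isin(self.codes, (2, 3)) & self.mask
        raise ValueError(f"unknown tracer {tracer!r}")


@dataclass
class OccupancyResult:
    """Percent of whole-brain volume per overlap category."""

    age_months: float | None
    percent: dict[int, float]  # category code -> % of brain volume
    tspo_total: float  # tspo_only + both
    amyloid_total: float  # amyloid_only + both


@dataclass
class TransitionFlow:
    """Per-tracer inter-age volume flows, as % of whole-brain volume."""

    age_from: float
    age_to: float
    per_tracer: dict[str, dict[str, float]]  # tracer -> {persisting, new, disappeared}
    category_matrix: pd.DataFrame  # 4x4 % of brain volume, rows=from, cols=to


def combine_categories(
    tspo: BinaryMap, amyloid: BinaryMap, brain_mask: np.ndarray, age_months: float | None = None
) -> CategoryMap:
    """Merge the two tracers' significance maps by the fixed truth table."""
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if tspo.elevated.shape != amyloid.elevated.shape or tspo.elevated.shape != brain_mask.shape:
        raise ValueError("binary maps and brain mask must share one grid")
    codes = np.zeros(brain_mask.shape, dtype=np.int8)
    codes[tspo.elevated & brain_mask] += 1
    codes[amyloid.elevated & brain_mask] += 2
    if age_months is None:
        age_months = tspo.age_months
    return CategoryMap(codes=codes, mask=brain_mask, age_months=age_months)


def occupancy(cat: CategoryMap, brain_mask: np.ndarray | None = None) -> OccupancyResult:
    """%-occupancy of each category relative to the whole brain volume."""
    mask = cat.mask if brain_mask is None else np.asarray(brain_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty brain mask")
    codes = cat.codes[mask]
    percent = {c: 100.0 * float((codes == c).sum()) / n for c in CATEGORY_LEGEND}
    return OccupancyResult(
        age_months=cat.age_months,
        percent=percent,
        tspo_total=percent[1] + percent[3],
        amyloid_total=percent[2] + percent[3],
    )


def dice_binary(a: BinaryMap | np.ndarray, b: BinaryMap | np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) of two binary maps (0 if both empty)."""
    av = (a.elevated if isinstance(a, BinaryMap) else np.asarray(a, dtype=bool))
    bv = (b.elevated if isinstance(b, BinaryMap) else np.asarray(b, dtype=bool))
    if av.shape != bv.shape:
        raise ValueError("maps must share one grid")
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        log.info("dice_binary: both maps empty; returning 0 by convention")
        return 0.0
    return 2.0 * int((av & bv).sum()) / denom


def dice_continuous(a: TScoreMap, b: TScoreMap, brain_mask: np.ndarray | None = None) -> float:
    """Fuzzy Dice of two T-score fields over the brain mask.

    ``2 * sum(min(a+, b+)) / (sum(a+) + sum(b+))`` with ``x+ = max(x, 0)``;
    on 0/1-valued fields this equals :func:`dice_binary` exactly.
    """
    mask = a.mask if brain_mask is None else np.asarray(brain_mask, dtype=bool)
    if a.t.shape != b.t.shape or a.t.shape != mask.shape:
        raise ValueError("maps must share one grid")
    ap = np.maximum(a.t[mask], 0.0)
    bp = np.maximum(b.t[mask], 0.0)
    denom = ap.sum() + bp.sum()
    if denom == 0:
        log.info("dice_continuous: both positive parts vanish; returning 0 by convention")
        return 0.0
    return float(2.0 * np.minimum(ap, bp).sum() / denom)


def transition_flows(
    cat_from: CategoryMap, cat_to: CategoryMap, brain_mask: np.ndarray | None = None
) -> TransitionFlow:
    """Classify voxels as persisting / newly presenting / disappeared per tracer.

    Percentages are relative to whole-brain volume, so for each tracer
    ``occupancy(to) = occupancy(from) + new - disappeared`` holds exactly.
    A full 4x4 category transition matrix is included for completeness.
    """
    if cat_from.codes.shape != cat_to.codes.shape:
        raise ValueError("category maps must share one grid")
    if cat_from.age_months is None or cat_to.age_months is None:
        raise ValueError("category maps must carry their age groups")
    if cat_to.age_months <= cat_from.age_months:
        raise ValueError(
            f"age_to ({cat_to.age_months}) must exceed age_from ({cat_from.age_months})"
        )
    mask = cat_from.mask if brain_mask is None else np.asarray(brain_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty brain mask")

    per_tracer = {}
    for tracer in ("tspo", "amyloid"):
        was = cat_from.tracer_elevated(tracer)[mask]
        now = cat_to.tracer_elevated(tracer)[mask]
        per_tracer[tracer] = {
            "persisting": 100.0 * float((was & now).sum()) / n,
            "new": 100.0 * float((~was & now).sum()) / n,
            "disappeared": 100.0 * float((was & ~now).sum()) / n,
        }

    cf = cat_from.codes[mask]
    ct = cat_to.codes[mask]
    matrix = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            matrix[i, j] = 100.0 * float(((cf == i) & (ct == j)).sum()) / n
    category_matrix = pd.DataFrame(
        matrix,
        index=[CATEGORY_LEGEND[i] for i in range(4)],
        columns=[CATEGORY_LEGEND[j] for j in range(4)],
    )
    return TransitionFlow(
        age_from=float(cat_from.age_months),
        age_to=float(cat_to.age_months),
        per_tracer=per_tracer,
        category_matrix=category_matrix,
    )
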