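"""Category maps, occupancy percentages, Dice coefficients, transition flows."""

import math

import numpy as np
import pytest

from dualpet.overlap import (
    combine_categories,
    dice_binary,
    dice_continuous,
    occupancy,
    transition_flows,
)
from dualpet.voxelstats import BinaryMap, TScoreMap

SHAPE = (6, 6, 6)


def _bmap(elevated, mask=None, age=None):
    elevated = np.asarray(elevated, dtype=bool)
    if mask is None:
        mask = np.ones(elevated.shape, dtype=bool)
    return BinaryMap(
        elevated=elevated, t_threshold=2.0, q=0.05,
        n_significant=int(elevated.sum()), mask=mask, age_months=age,
    )


def _tmap(t, mask=None):
    t = np.asarray(t, dtype=float)
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    from scipy import stats

    p = np.where(mask, stats.t.sf(t, 14), np.nan)
    return TScoreMap(t=t, p_one_sided=p, df=14, mask=mask)


def _random_cat(rng, age=None):
    mask = np.ones(SHAPE, dtype=bool)
    tspo = _bmap(rng.random(SHAPE) < 0.4, age=age)
    amy = _bmap(rng.random(SHAPE) < 0.3, age=age)
    return combine_categories(tspo, amy, mask, age_months=age), tspo, amy


class TestCategories:
    def test_truth_table(self):
        mask = np.ones(SHAPE, dtype=bool)
        tspo = np.zeros(SHAPE, dtype=bool)
        amy = np.zeros(SHAPE, dtype=bool)
        tspo[0, 0, 0] = True               # -> code 1
        amy[1, 0, 0] = True                # -> code 2
        tspo[2, 0, 0] = amy[2, 0, 0] = True  # -> code 3
        cat = combine_categories(_bmap(tspo), _bmap(amy), mask)
        assert cat.codes[0, 0, 0] == 1
        assert cat.codes[1, 0, 0] == 2
        assert cat.codes[2, 0, 0] == 3
        assert cat.codes[3, 0, 0] == 0

    def test_empty_maps_give_all_zero(self):
        mask = np.ones(SHAPE, dtype=bool)
        cat = combine_categories(_bmap(np.zeros(SHAPE)), _bmap(np.zeros(SHAPE)), mask)
        assert not cat.codes.any()


class TestOccupancy:
    def test_all_neither(self):
        mask = np.ones(SHAPE, dtype=bool)
        cat = combine_categories(_bmap(np.zeros(SHAPE)), _bmap(np.zeros(SHAPE)), mask)
        occ = occupancy(cat)
        assert occ.percent[0] == 100.0
        assert occ.percent[1] == occ.percent[2] == occ.percent[3] == 0.0

    def test_half_mask_single_category(self):
        mask = np.ones(SHAPE, dtype=bool)
        tspo = np.zeros(SHAPE, dtype=bool)
        tspo[:3] = True
        occ = occupancy(combine_categories(_bmap(tspo), _bmap(np.zeros(SHAPE)), mask))
        assert occ.percent[1] == pytest.approx(50.0)
        assert occ.percent[0] == pytest.approx(50.0)

    def test_partition_and_counting_oracle(self, rng):
        cat, _, _ = _random_cat(rng)
        occ = occupancy(cat)
        assert sum(occ.percent.values()) == pytest.approx(100.0, abs=1e-9)
        n = cat.mask.sum()
        for code in range(4):
            count = sum(
                1 for idx in np.ndindex(*SHAPE) if cat.mask[idx] and cat.codes[idx] == code
            )
            assert occ.percent[code] == pytest.approx(100.0 * count / n, abs=1e-12)

    def test_empty_mask_rejected(self, rng):
        cat, _, _ = _random_cat(rng)
        with pytest.raises(ValueError, match="empty"):
            occupancy(cat, np.zeros(SHAPE, dtype=bool))


class TestDice:
    def test_identical_disjoint_and_formula(self):
        a = np.zeros(SHAPE, dtype=bool)
        a[0] = True
        assert dice_binary(_bmap(a), _bmap(a)) == 1.0
        b = np.zeros(SHAPE, dtype=bool)
        b[1] = True
        assert dice_binary(_bmap(a), _bmap(b)) == 0.0
        # |A| = |B| = 4, |A ∩ B| = 2 -> 0.5
        x = np.zeros(SHAPE, dtype=bool)
        y = np.zeros(SHAPE, dtype=bool)
        x.flat[:4] = True
        y.flat[2:6] = True
        assert dice_binary(x, y) == 0.5

    def test_both_empty_defined_as_zero(self):
        z = np.zeros(SHAPE, dtype=bool)
        assert dice_binary(z, z) == 0.0

    def test_continuous_identity_and_disjoint(self, rng):
        t = np.abs(rng.normal(size=SHAPE))
        assert dice_continuous(_tmap(t), _tmap(t)) == pytest.approx(1.0)
        a = np.zeros(SHAPE)
        b = np.zeros(SHAPE)
        a[:3] = 1.5
        b[3:] = 2.0
        assert dice_continuous(_tmap(a), _tmap(b)) == 0.0

    def test_continuous_equals_binary_on_binary_fields(self, rng):
        for _ in range(10):
            a = rng.random(SHAPE) < 0.4
            b = rng.random(SHAPE) < 0.4
            db = dice_binary(a, b)
            dc = dice_continuous(_tmap(a.astype(float)), _tmap(b.astype(float)))
            assert dc == pytest.approx(db, abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(10):
            ta, tb = rng.normal(size=SHAPE), rng.normal(size=SHAPE)
            d1 = dice_continuous(_tmap(ta), _tmap(tb))
            d2 = dice_continuous(_tmap(tb), _tmap(ta))
            assert d1 == d2
            assert 0.0 <= d1 <= 1.0
        a = rng.random(SHAPE) < 0.3
        b = rng.random(SHAPE) < 0.3
        assert dice_binary(a, b) == dice_binary(b, a)

    def test_binary_dice_reproducible_from_category_map(self, rng):
        # 2 * %both / (%tspo_total + %amyloid_total) recovers the Dice of the
        # two binary maps from the category map alone.
        cat, tspo, amy = _random_cat(rng)
        occ = occupancy(cat)
        denom = occ.tspo_total + occ.amyloid_total
        from_cat = 2.0 * occ.percent[3] / denom if denom else 0.0
        assert from_cat == pytest.approx(dice_binary(tspo, amy), abs=1e-9)


class TestTransitions:
    def test_no_change(self, rng):
        cat1, _, _ = _random_cat(rng, age=5.0)
        cat2 = type(cat1)(codes=cat1.codes.copy(), mask=cat1.mask, age_months=8.0)
        flow = transition_flows(cat1, cat2)
        for tracer in ("tspo", "amyloid"):
            assert flow.per_tracer[tracer]["new"] == 0.0
            assert flow.per_tracer[tracer]["disappeared"] == 0.0

    def test_empty_to_full(self):
        mask = np.ones(SHAPE, dtype=bool)
        empty = combine_categories(
            _bmap(np.zeros(SHAPE)), _bmap(np.zeros(SHAPE)), mask, age_months=5.0
        )
        full = combine_categories(
            _bmap(np.ones(SHAPE)), _bmap(np.ones(SHAPE)), mask, age_months=8.0
        )
        flow = transition_flows(empty, full)
        for tracer in ("tspo", "amyloid"):
            assert flow.per_tracer[tracer]["new"] == pytest.approx(100.0)
            assert flow.per_tracer[tracer]["disappeared"] == 0.0

    def test_bookkeeping_oracle_and_conservation(self, rng):
        cat1, _, _ = _random_cat(rng, age=8.0)
        cat2, _, _ = _random_cat(rng, age=13.0)
        flow = transition_flows(cat1, cat2)
        n = cat1.mask.sum()
        for tracer in ("tspo", "amyloid"):
            was = cat1.tracer_elevated(tracer)
            now = cat2.tracer_elevated(tracer)
            persist = new = gone = 0
            for idx in np.ndindex(*SHAPE):
                if not cat1.mask[idx]:
                    continue
                if was[idx] and now[idx]:
                    persist += 1
                elif now[idx]:
                    new += 1
                elif was[idx]:
                    gone += 1
            ft = flow.per_tracer[tracer]
            assert ft["persisting"] == pytest.approx(100.0 * persist / n, abs=1e-12)
            assert ft["new"] == pytest.approx(100.0 * new / n, abs=1e-12)
            assert ft["disappeared"] == pytest.approx(100.0 * gone / n, abs=1e-12)
            # occupancy conservation
            occ_from = occupancy(cat1)
            occ_to = occupancy(cat2)
            totals = {"tspo": "tspo_total", "amyloid": "amyloid_total"}[tracer]
            assert getattr(occ_to, totals) == pytest.approx(
                getattr(occ_from, totals) + ft["new"] - ft["disappeared"], abs=1e-9
            )
        assert flow.category_matrix.to_numpy().sum() == pytest.approx(100.0, abs=1e-9)

    def test_same_age_rejected(self, rng):
        cat1, _, _ = _random_cat(rng, age=5.0)
        cat2, _, _ = _random_cat(rng, age=5.0)
        with pytest.raises(ValueError, match="exceed"):
            transition_flows(cat1, cat2)
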