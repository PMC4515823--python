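"""Winner/loser classification and the net-loss exposure accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palmx.exposure import (Category, classify_exposure, delta_suitability,
                            stack_richness, summarize_species)
from palmx.grid import Grid
from palmx.rasters import Raster
from palmx.sdm import build_dispersal_mask
from palmx.sdm.threshold import RangeMask


def raster(values):
    values = np.asarray(values, dtype=float)
    return Raster(Grid(*values.shape, 10.0), values)


class TestDelta:
    def test_identity_future_gives_zero_delta(self):
        b = raster(np.random.default_rng(0).random((5, 5)))
        d = delta_suitability(b, b.copy_with(b.values.copy()))
        np.testing.assert_array_equal(d.values, 0.0)

    def test_cellwise_difference(self):
        d = delta_suitability(raster([[0.8]]), raster([[0.3]]))
        assert d.values[0, 0] == pytest.approx(-0.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = raster(rng.random((4, 4))), raster(rng.random((4, 4)))
        np.testing.assert_allclose(delta_suitability(a, b).values,
                                   -delta_suitability(b, a).values)

    def test_nodata_propagates(self):
        a = raster([[0.5, np.nan], [0.2, 0.9]])
        b = raster([[0.1, 0.7], [np.nan, 0.4]])
        d = delta_suitability(a, b)
        assert np.isnan(d.values[0, 1]) and np.isnan(d.values[1, 0])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            delta_suitability(raster(np.zeros((3, 3))),
                              raster(np.zeros((4, 4))))


def mask_of(current, buffer_ring=None):
    current = np.asarray(current, dtype=bool)
    grid = Grid(*current.shape, 10.0)
    if buffer_ring is None:
        return RangeMask("sp", grid, current)
    reachable = current | np.asarray(buffer_ring, dtype=bool)
    return RangeMask("sp", grid, current, buffer_km=100.0,
                     reachable=reachable)


class TestClassify:
    def test_sign_only_rule_in_range(self):
        # in-range deltas (-0.2, 0, +0.1) -> loser, unchanged, winner
        delta = raster([[-0.2, 0.0, 0.1]])
        m = mask_of([[True, True, True]])
        cats = classify_exposure(delta, m)
        assert list(cats[0]) == [Category.LOCAL_LOSER, Category.UNCHANGED,
                                 Category.LOCAL_WINNER]

    def test_buffer_ring_gains_only(self):
        delta = raster([[0.01, -0.4]])
        m = mask_of([[False, False]], buffer_ring=[[True, True]])
        cats = classify_exposure(delta, m)
        assert cats[0, 0] == Category.IMMIGRANT_WINNER
        assert cats[0, 1] == Category.OUTSIDE

    def test_mixed_winner_loser_map_accepted(self):
        # a species may lose in one cell and win in another; no species-
        # level coercion happens
        delta = raster([[-0.3, 0.3]])
        cats = classify_exposure(delta, mask_of([[True, True]]))
        assert {Category.LOCAL_LOSER, Category.LOCAL_WINNER} == set(cats[0])

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(12)
        delta = raster(rng.uniform(-1, 1, size=(12, 12)))
        current = rng.random((12, 12)) > 0.7
        base = RangeMask("sp", Grid(12, 12, 10.0), current)
        m = build_dispersal_mask(base, 30.0)
        cats = classify_exposure(delta, m)
        in_range = (cats == Category.LOCAL_LOSER) | \
            (cats == Category.LOCAL_WINNER) | (cats == Category.UNCHANGED)
        np.testing.assert_array_equal(in_range, m.current)
        assert (cats[~m.reachable] == Category.OUTSIDE).all()
        n_loser = (cats == Category.LOCAL_LOSER).sum()
        n_winner = (cats == Category.LOCAL_WINNER).sum()
        n_unch = (cats == Category.UNCHANGED).sum()
        assert n_loser + n_winner + n_unch == m.current.sum()


class TestSummaries:
    def test_hand_enumerated_net_formula(self):
        # 10 range cells, 7 losers, 3 buffer gains -> 70% in-range loss and
        # (7 - 3) / 10 = 40% overall loss
        current = np.zeros((4, 5), dtype=bool)
        current[:2, :] = True  # 10 cells
        ring = np.zeros((4, 5), dtype=bool)
        ring[3, :3] = True
        delta = np.zeros((4, 5))
        delta[0, :5] = -0.1
        delta[1, :2] = -0.1     # 7 losers
        delta[1, 2:] = +0.2     # 3 in-range winners
        delta[3, :3] = +0.3     # 3 buffer gains
        m = mask_of(current, buffer_ring=ring)
        cats = classify_exposure(raster(delta), m)
        s = summarize_species(cats, m)
        assert s.n_range_cells == 10 and s.n_loser_cells == 7
        assert s.n_buffer_gain_cells == 3
        assert s.pct_loss_in_range == pytest.approx(70.0)
        assert s.pct_overall_loss == pytest.approx(40.0)

    def test_negative_net_loss_reported_as_is(self):
        # 2 losers, 5 buffer gains, 10 range cells -> -30% (net expansion)
        current = np.zeros((4, 5), dtype=bool)
        current[:2, :] = True
        ring = np.zeros((4, 5), dtype=bool)
        ring[3, :] = True
        delta = np.zeros((4, 5))
        delta[0, :2] = -0.1
        delta[3, :] = +0.1
        m = mask_of(current, buffer_ring=ring)
        s = summarize_species(classify_exposure(raster(delta), m), m)
        assert s.pct_overall_loss == pytest.approx(-30.0)

    def test_no_change_gives_zeros(self):
        current = np.ones((3, 3), dtype=bool)
        m = mask_of(current)
        s = summarize_species(
            classify_exposure(raster(np.zeros((3, 3))), m), m)
        assert s.pct_loss_in_range == 0.0 and s.pct_overall_loss == 0.0

    def test_no_dispersal_forces_zero_buffer_gain(self):
        current = np.zeros((3, 3), dtype=bool)
        current[1, 1] = True
        m = mask_of(current)
        delta = np.full((3, 3), 0.5)
        delta[1, 1] = -0.5
        cats = classify_exposure(raster(delta), m)
        s = summarize_species(cats, m)
        assert s.n_buffer_gain_cells == 0
        assert s.pct_overall_loss == s.pct_loss_in_range == 100.0

    def test_empty_range_rejected(self):
        m = mask_of(np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="empty current range"):
            summarize_species(np.zeros((3, 3), dtype=np.uint8), m)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 20))
    def test_net_loss_never_exceeds_in_range_loss(self, seed):
        # buffer colonisation can only reduce the net statistic
        rng = np.random.default_rng(seed)
        current = rng.random((8, 8)) > 0.6
        if not current.any():
            current[0, 0] = True
        base = RangeMask("sp", Grid(8, 8, 10.0), current)
        m = build_dispersal_mask(base, 20.0)
        delta = raster(rng.uniform(-1, 1, size=(8, 8)))
        s = summarize_species(classify_exposure(delta, m), m)
        assert s.pct_overall_loss <= s.pct_loss_in_range + 1e-12


class TestRichness:
    def test_all_losers_flagged(self):
        current = np.ones((2, 2), dtype=bool)
        masks = [mask_of(current)] * 3
        cats = [np.full((2, 2), Category.LOCAL_LOSER, dtype=np.uint8)] * 3
        maps = stack_richness(cats, masks)
        assert (maps.losers == 3).all()
        np.testing.assert_array_equal(maps.proportion_lost, 1.0)
        assert maps.high_loss.all()

    def test_eighty_percent_boundary_inclusive(self):
        current = np.ones((1, 1), dtype=bool)
        masks = [mask_of(current)] * 5
        cats = [np.full((1, 1), Category.LOCAL_LOSER, dtype=np.uint8)] * 4 \
            + [np.full((1, 1), Category.LOCAL_WINNER, dtype=np.uint8)]
        maps = stack_richness(cats, masks)
        assert maps.proportion_lost[0, 0] == pytest.approx(0.8)
        assert maps.high_loss[0, 0]

    def test_richness_double_counting_identity(self):
        rng = np.random.default_rng(3)
        masks, cats = [], []
        for _ in range(6):
            cur = rng.random((7, 7)) > 0.5
            m = mask_of(cur)
            delta = raster(rng.uniform(-1, 1, size=(7, 7)))
            masks.append(m)
            cats.append(classify_exposure(delta, m))
        maps = stack_richness(cats, masks)
        assert maps.richness.sum() == sum(m.current.sum() for m in masks)
        assert (maps.losers <= maps.richness).all()

    def test_empty_species_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stack_richness([], [])
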