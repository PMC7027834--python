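import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import gap_mask_oracle, flood_fill_components, label_sets
from argogaps import (bin_profiles, annual_gap_mask, build_gap_stack,
                      persistence, extract_coldspots, coldspot_summary,
                      AnnualDensity, GapStack, ColdspotMap, StaticMasks,
                      sector_masks, cell_areas)


def density(counts, year=2010):
    return AnnualDensity(year=year, counts=np.asarray(counts))


class TestBinProfiles:
    def test_counts_and_wrap(self, grid):
        df = pd.DataFrame({
            "timestamp": ["2010-03-01T00:00:00"] * 3 + ["2010-06-01", "2011-06-01"],
            "lat": [0.5, 0.5, 0.5, 0.5, 0.5],
            "lon": [0.5, 0.5, 0.5, 359.5, 0.5],
        })
        d = bin_profiles(df, grid, 2010)
        r, c = grid.cell_of(0.5, 0.5)
        assert d.counts[r, c] == 3
        rw, cw = grid.cell_of(0.5, -0.5)
        assert d.counts[rw, cw] == 1          # lon 359.5 wraps to -0.5
        assert d.total == 4                    # the 2011 profile is ignored

    def test_bad_rows_skipped(self, grid, caplog):
        df = pd.DataFrame({
            "timestamp": ["2010-01-01", "not a date", "2010-01-01"],
            "lat": [10.5, 10.5, 95.0],
            "lon": [10.5, 10.5, 10.5],
        })
        with caplog.at_level("WARNING"):
            d = bin_profiles(df, grid, 2010)
        assert d.total == 1
        assert "skipped" in caplog.text and "rejected" in caplog.text

    def test_empty(self, grid):
        df = pd.DataFrame({"timestamp": [], "lat": [], "lon": []})
        assert bin_profiles(df, grid, 2010).total == 0


class TestAnnualGapMask:
    def test_all_zero_counts(self):
        ocean = np.array([[True, True, False]])
        gap = annual_gap_mask(density(np.zeros((1, 3), int)), ocean)
        assert gap.tolist() == [[True, True, False]]

    def test_all_positive_ties(self):
        """Equal positive counts: strict < excludes ties at the threshold."""
        ocean = np.ones((1, 5), bool)
        counts = np.array([[2, 2, 2, 2, 0]])
        gap = annual_gap_mask(density(counts), ocean)
        assert gap.tolist() == [[False, False, False, False, True]]

    def test_interpolated_quintile_example(self):
        """Positive counts {1,1,1,2,2,3,4,5}: T = 1.0, so only zeros gap."""
        counts = np.array([[1, 1, 1, 2, 2, 3, 4, 5, 0]])
        ocean = np.ones((1, 9), bool)
        gap = annual_gap_mask(density(counts), ocean)
        assert gap.sum() == 1 and gap[0, 8]

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("lam", [0.5, 3.0, 20.0])
    def test_matches_oracle(self, seed, lam):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam, size=(23, 31))
        ocean = rng.random((23, 31)) < 0.8
        got = annual_gap_mask(density(counts), ocean)
        want = gap_mask_oracle(counts, ocean)
        np.testing.assert_array_equal(got, want)

    def test_errors(self):
        with pytest.raises(ValueError):
            annual_gap_mask(density(np.zeros((2, 2), int)), np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            annual_gap_mask(density(np.zeros((2, 2), int)), np.ones((2, 2), bool), q=1.5)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 10))
    @settings(max_examples=30, deadline=None)
    def test_unsampled_monotone_under_uniform_raise(self, seed, c):
        """Adding a positive constant to every count cannot increase the
        number of un-sampled (zero-count) cells."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, size=(10, 10))
        ocean = np.ones((10, 10), bool)
        before = int((annual_gap_mask(density(counts), ocean) & (counts == 0)).sum())
        raised = counts + c
        after = int((annual_gap_mask(density(raised), ocean) & (raised == 0)).sum())
        assert after <= before


class TestPersistence:
    @pytest.mark.parametrize("k,passes", [(12, True), (10, True), (9, False)])
    def test_year_fractions(self, k, passes):
        gap = np.zeros((12, 1, 1), bool)
        gap[:k, 0, 0] = True
        stack = GapStack(years=tuple(range(2005, 2017)), gap=gap)
        p = persistence(stack)[0, 0]
        assert p == pytest.approx(k / 12)
        assert bool(p >= 0.8) == passes

    def test_exact_multiples(self, rng):
        gap = rng.random((12, 9, 9)) < 0.4
        stack = GapStack(years=tuple(range(12)), gap=gap)
        p = persistence(stack)
        np.testing.assert_array_equal(p * 12, np.round(p * 12))


class TestExtractColdspots:
    def test_block(self):
        pers = np.zeros((20, 20))
        pers[5:10, 5:10] = 1.0
        cm = extract_coldspots(pers, min_cells=25)
        assert cm.n_components == 1
        assert cm.table["n_cells"].item() == 25

    @pytest.mark.parametrize("n,expect", [(24, 0), (25, 1), (26, 1)])
    def test_min_cells_boundary(self, n, expect):
        pers = np.zeros((10, 40))
        pers[3, :n] = 1.0
        cm = extract_coldspots(pers, min_cells=25, wrap=False)
        assert cm.n_components == expect

    def test_diagonal_touch_connectivity(self):
        """13- and 12-cell patches touching only diagonally merge to one
        25-cell component under 8-connectivity, and vanish under 4."""
        pers = np.zeros((30, 30))
        pers[2:4, 2:8] = 1.0            # 12 cells: rows 2-3 x cols 2-7
        pers[4:5, 8:21] = 1.0           # 13 cells: row 4 x cols 8-20
        cm8 = extract_coldspots(pers, connectivity=8, min_cells=25, wrap=False)
        assert cm8.n_components == 1 and cm8.table["n_cells"].item() == 25
        cm4 = extract_coldspots(pers, connectivity=4, min_cells=25, wrap=False)
        assert cm4.n_components == 0

    def test_all_zero(self):
        cm = extract_coldspots(np.zeros((10, 10)))
        assert cm.n_components == 0 and not cm.mask.any()

    def test_wrap_seam_merge(self):
        pers = np.zeros((10, 36))
        pers[2:7, 0:3] = 1.0    # 15 cells at the west edge
        pers[2:7, 34:36] = 1.0  # 10 cells at the east edge, adjacent via wrap
        cm = extract_coldspots(pers, min_cells=25)
        assert cm.n_components == 1 and cm.table["n_cells"].item() == 25
        assert extract_coldspots(pers, min_cells=25, wrap=False).n_components == 0

    def test_label_order_by_area(self):
        pers = np.zeros((40, 40))
        pers[0:5, 0:6] = 1.0    # 30 cells
        pers[20:25, 0:5] = 1.0  # 25 cells
        cm = extract_coldspots(pers, wrap=False)
        assert cm.table["n_cells"].tolist() == [30, 25]
        assert cm.labels[0, 0] == 1 and cm.labels[20, 0] == 2

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        binary = rng.random((50, 50)) < 0.45
        cm = extract_coldspots(binary.astype(float), threshold=0.5,
                               min_cells=1, connectivity=connectivity)
        want = set(flood_fill_components(binary, connectivity, wrap=True))
        assert label_sets(cm.labels) == want

    def test_invalid_persistence(self):
        with pytest.raises(ValueError):
            extract_coldspots(np.array([[1.5]]))


class TestColdspotSummary:
    def _masks(self, grid):
        ocean = np.ones(grid.shape, bool)
        depth = np.full(grid.shape, 3000.0)
        eez = np.zeros(grid.shape, int)
        return ocean, depth, eez

    def test_single_eez(self, grid, areas):
        ocean, depth, eez = self._masks(grid)
        eez[80:90, 40:60] = 7
        labels = np.zeros(grid.shape, int)
        labels[82:87, 45:50] = 1
        cm = ColdspotMap(labels=labels, table=pd.DataFrame(
            [{"label": 1, "n_cells": 25, "area_km2": areas[labels == 1].sum()}]))
        masks = StaticMasks(ocean=ocean, depth_m=depth, eez_id=eez,
                            sector_id=sector_masks(grid))
        s = coldspot_summary(cm, masks, areas)
        assert s["eez_fraction"] == pytest.approx(1.0)
        assert s["eez_ranking"]["zone"].iloc[0] == 7
        assert s["total_area_km2"] == pytest.approx(areas[labels == 1].sum())

    def test_poleward_fraction_matches_brute_force(self, grid, areas):
        """Coldspot straddling 60N: poleward-of-60 fraction equals a direct
        latitude-dependent area sum."""
        ocean, depth, eez = self._masks(grid)
        labels = np.zeros(grid.shape, int)
        r60, _ = grid.cell_of(60.5, 0)
        labels[r60 - 5:r60 + 5, 10:20] = 1
        cm = ColdspotMap(labels=labels, table=pd.DataFrame(
            [{"label": 1, "n_cells": 100, "area_km2": areas[labels == 1].sum()}]))
        masks = StaticMasks(ocean=ocean, depth_m=depth, eez_id=eez,
                            sector_id=sector_masks(grid))
        s = coldspot_summary(cm, masks, areas)
        lat2d = np.repeat(grid.lat_centers[:, None], grid.n_lon, axis=1)
        want = areas[(labels == 1) & (np.abs(lat2d) > 60)].sum() / areas[labels == 1].sum()
        assert s["poleward_60_fraction"] == pytest.approx(want, rel=1e-12)

    def test_empty_coldspots(self, grid, areas):
        ocean, depth, eez = self._masks(grid)
        cm = ColdspotMap(labels=np.zeros(grid.shape, int),
                         table=pd.DataFrame(columns=["label", "n_cells", "area_km2"]))
        masks = StaticMasks(ocean=ocean, depth_m=depth, eez_id=eez,
                            sector_id=sector_masks(grid))
        s = coldspot_summary(cm, masks, areas)
        assert s["total_area_km2"] == 0
        assert (s["by_sector"]["fraction"] == 0).all()
        assert s["eez_fraction"] == 0
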