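"""Generator tests run on reduced worlds (lower profile intensity, few
species, short tracks) so the whole suite stays fast; the full-scale
defaults are exercised once by the acceptance tests."""

import numpy as np
import pandas as pd
import pytest

from argogaps import (Scenario, PlantedColdspot, gen_world, gen_profiles,
                      gen_species, gen_tracks, cap_area_km2, cell_areas,
                      recovery_scenario, haversine_km)
from argogaps.synthetic import _cap_presence, TELEMETRY_TAXA


SMALL = dict(n_species_per_taxon=2, animals_per_species=2, points_per_animal=25,
             base_intensity=1.0)


class TestWorld:
    def test_determinism(self):
        a = gen_world(Scenario(seed=5))
        b = gen_world(Scenario(seed=5))
        np.testing.assert_array_equal(a.ocean, b.ocean)
        np.testing.assert_array_equal(a.eez_id, b.eez_id)

    def test_all_ocean(self):
        w = gen_world(Scenario(seed=1, ocean_fraction=1.0))
        assert w.ocean.all()
        assert np.isfinite(w.depth_m).all() and (w.depth_m >= 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ocean_area_fraction(self, seed, areas):
        scn = Scenario(seed=seed, ocean_fraction=0.7)
        w = gen_world(scn)
        frac = areas[w.ocean].sum() / areas.sum()
        assert frac == pytest.approx(0.7, abs=0.05)

    def test_depth_defined_on_ocean(self):
        w = gen_world(Scenario(seed=3))
        assert np.isfinite(w.depth_m[w.ocean]).all()
        assert (w.depth_m[w.ocean] >= 0).all()
        assert np.isnan(w.depth_m[~w.ocean]).all()

    def test_planted_cells_forced_ocean(self):
        scn = recovery_scenario(seed=2)
        w = gen_world(scn)
        for p in scn.planted_coldspots:
            rr, cc = p.cells(scn.grid.shape)
            assert w.ocean[rr, cc].all()

    def test_adjacent_planted_rejected(self):
        with pytest.raises(ValueError):
            Scenario(planted_coldspots=(
                PlantedColdspot(10, 10, 5, 5),
                PlantedColdspot(10, 15, 5, 5),   # touches the first block
            ))


class TestProfiles:
    def test_zero_intensity(self):
        scn = Scenario(seed=1, base_intensity=0.0)
        w = gen_world(scn)
        assert len(gen_profiles(scn, w)) == 0

    def test_poisson_total_concentration(self):
        """Realized total within 4*sqrt(lambda) of the expected count."""
        scn = Scenario(seed=11, base_intensity=0.05, lat_bias=0.0,
                       years=(2010,))
        w = gen_world(scn)
        lam = 0.05 * w.ocean.sum()
        n = len(gen_profiles(scn, w))
        assert abs(n - lam) < 4 * np.sqrt(lam)

    def test_planted_region_empty_in_gap_years(self, grid):
        scn = recovery_scenario(seed=4, base_intensity=1.0)
        w = gen_world(scn)
        prof = gen_profiles(scn, w)
        rows, cols = grid.cell_of(prof["lat"].to_numpy(), prof["lon"].to_numpy())
        years = pd.to_datetime(prof["timestamp"]).dt.year.to_numpy()
        for i, p in enumerate(scn.planted_coldspots):
            region = np.zeros(grid.shape, bool)
            rr, cc = p.cells(grid.shape)
            region[rr, cc] = True
            inside = region[rows, cols]
            for y in scn.gap_years(i):
                assert not (inside & (years == y)).any()

    def test_determinism(self):
        scn = Scenario(seed=9, base_intensity=0.2, years=(2010, 2011))
        w = gen_world(scn)
        a, b = gen_profiles(scn, w), gen_profiles(scn, w)
        pd.testing.assert_frame_equal(a, b)


class TestSpecies:
    def test_cap_area_closed_form(self, grid, areas):
        """Rasterized 5-degree equatorial cap within 10% of 2*pi*R^2*(1-cos 5)."""
        pres = _cap_presence(grid, lon0=0.0, lat0=0.0, radius_deg=5.0)
        assert areas[pres].sum() == pytest.approx(cap_area_km2(5.0), rel=0.10)

    def test_global_cap(self, grid):
        pres = _cap_presence(grid, 0.0, 0.0, 180.0)
        assert pres.all()

    def test_table_structure(self):
        scn = Scenario(seed=2, **SMALL)
        w = gen_world(scn)
        table, presences, caps = gen_species(scn, w)
        assert len(table) == 16  # 2 per taxon x 8 taxa
        assert set(table["taxon"].unique()) == set(
            ["tuna_billfishes", "sharks_rays", "pinnipeds", "cetaceans",
             "penguins", "flying_seabirds", "turtles", "sirenians"])
        for sid in table["species_id"]:
            assert presences[sid].dtype == bool
            assert not (presences[sid] & ~w.ocean).any()  # ocean-restricted

    def test_missing_depth_fraction_zero(self):
        scn = Scenario(seed=2, missing_depth_fraction=0.0, **{
            k: v for k, v in SMALL.items() if k != "base_intensity"})
        w = gen_world(scn)
        table, _, _ = gen_species(scn, w)
        assert table["max_dive_depth_m"].notna().all()


class TestTracks:
    def test_confinement_and_determinism(self, grid):
        scn = Scenario(seed=6, **SMALL)
        w = gen_world(scn)
        table, presences, caps = gen_species(scn, w)
        tr = gen_tracks(scn, table, caps)
        assert set(table.loc[table["taxon"].isin(TELEMETRY_TAXA), "species_id"]) \
            == set(tr["species_id"].unique())
        for sid, grp in tr.groupby("species_id"):
            lon0, lat0, radius = caps[sid]
            d = haversine_km(lat0, lon0, grp["lat"].to_numpy(), grp["lon"].to_numpy())
            assert (d <= np.deg2rad(radius) * grid.radius_km * 1.0001).all()
        tr2 = gen_tracks(scn, table, caps)
        pd.testing.assert_frame_equal(tr, tr2)

    def test_high_concentration_near_geodesic(self):
        """kappa -> inf: successive bearings stay almost constant."""
        scn = Scenario(seed=6, kappa=1e6, step_km=30.0, **{
            k: v for k, v in SMALL.items() if k != "base_intensity"})
        w = gen_world(scn)
        table, _, caps = gen_species(scn, w)
        sid = table.loc[table["taxon"] == "pinnipeds", "species_id"].iloc[0]
        # widen the cap so no reflection interferes with the geodesic
        caps = dict(caps); caps[sid] = (caps[sid][0], caps[sid][1], 170.0)
        one = table[table["species_id"] == sid]
        tr = gen_tracks(scn, one, caps)
        a0 = tr[tr["animal_id"] == tr["animal_id"].iloc[0]]
        lats = np.deg2rad(a0["lat"].to_numpy())
        # a geodesic crosses the start latitude at most twice
        sign_changes = np.abs(np.diff(np.sign(np.diff(lats)))).sum() / 2
        assert sign_changes <= 2

    def test_points_per_animal(self):
        scn = Scenario(seed=3, **SMALL)
        w = gen_world(scn)
        table, _, caps = gen_species(scn, w)
        tr = gen_tracks(scn, table, caps)
        per = tr.groupby("animal_id").size()
        assert (per == scn.points_per_animal).all()
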