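import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scomber.movement import (
    gas_daily_step,
    migration_step,
    profitability,
    random_walk_in_area,
    search_radius_patches,
    spawning_move,
    v_min,
)
from scomber.population import Stage
from scomber.seascape import Seascape, distance_field

from conftest import make_adult


class TestVmin:
    def test_printed_allometry_at_maturity_length(self, params):
        assert v_min(26.2, params) == pytest.approx(1.847, abs=0.002)

    def test_printed_allometry_at_asymptotic_length(self, params):
        assert v_min(42.4, params) == pytest.approx(2.49, abs=0.005)

    def test_non_positive_length_rejected(self, params):
        with pytest.raises(ValueError):
            v_min(0.0, params)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.5, 41.0), st.floats(0.1, 1.0))
    def test_strictly_increasing_in_length(self, params, L, dL):
        assert v_min(L + dL, params) > v_min(L, params)


class TestMigration:
    def make_corridor(self, params):
        # one open east-west corridor, destination at the west end
        sea = Seascape(
            depth=np.full((3, 30), -300.0),
            lat=np.full((3, 30), 55.0),
            lon=np.zeros((3, 30)),
        )
        sea.SST[:] = 12.0
        R = distance_field(sea, (1, 0))
        return sea, R

    def test_moves_exactly_search_radius_down_gradient(self, params):
        sea, R = self.make_corridor(params)
        # length chosen so the per-step search radius is (just over) 3 patches
        L = 1.0001 * math.exp(math.log(3.0 / (2 * 0.15 * 4.01**0.35)) / 0.62)
        si = make_adult(params, L=L, x=20.0, y=1.0)
        si.migrating = True
        assert search_radius_patches(si, sea, params) == pytest.approx(3.0, abs=0.01)
        r0 = R[si.patch]
        for _ in range(3):
            migration_step(si, sea, R, params)
            assert R[si.patch] == max(r0 - 3, 0)
            r0 = R[si.patch]

    def test_larger_fish_arrive_no_later(self, params):
        sea, R = self.make_corridor(params)
        arrivals = {}
        for L in (28.0, 34.0, 40.0):
            si = make_adult(params, L=L, x=29.0, y=1.0)
            si.migrating = True
            steps = 0
            while si.migrating and steps < 50:
                migration_step(si, sea, R, params)
                steps += 1
            arrivals[L] = steps
        assert arrivals[40.0] <= arrivals[34.0] <= arrivals[28.0]

    def test_arrival_clears_flag(self, params):
        sea, R = self.make_corridor(params)
        si = make_adult(params, L=30.0, x=1.0, y=1.0)
        si.migrating = True
        si.migration_mode = "feeding"
        migration_step(si, sea, R, params)
        assert not si.migrating and si.migration_mode == ""

    def test_stop_distance_halts_short_of_target(self, params):
        sea, R = self.make_corridor(params)
        si = make_adult(params, L=30.0, x=20.0, y=1.0)
        si.migrating = True
        si.stop_distance = 5
        while si.migrating:
            migration_step(si, sea, R, params)
        assert R[si.patch] <= 5

    def test_shelf_constraint_restricts_candidates(self, params):
        sea, R = self.make_corridor(params)
        sea.depth[0, :] = -1000.0  # row 0 is off-shelf
        sea.shelf_edge = (sea.depth > -550) & (sea.depth < -50)
        si = make_adult(params, L=30.0, x=20.0, y=1.0)
        si.migrating = True
        for _ in range(5):
            migration_step(si, sea, R, params, constrain_shelf=True)
            assert sea.shelf_edge[si.patch]


class TestProfitability:
    def test_half_saturation_identity(self, params, open_sea):
        open_sea.X[:] = params.h
        open_sea.p_photo[:] = 1.0
        assert profitability(open_sea, 5, 5, params) == pytest.approx(0.5)

    def test_cold_water_zeroed(self, params, open_sea):
        open_sea.SST[3, 3] = 5.0
        assert profitability(open_sea, 3, 3, params) == 0.0

    def test_density_dependence_lowers_cue(self, params, open_sea):
        base = profitability(open_sea, 5, 5, params)
        open_sea.D[5, 5] = 1e10
        low = profitability(open_sea, 5, 5, params)
        open_sea.D[5, 5] = 2e10
        lower = profitability(open_sea, 5, 5, params)
        assert base > low > lower

    def test_land_is_worthless(self, params, open_sea):
        open_sea.ocean[0, 0] = False
        assert profitability(open_sea, 0, 0, params) == 0.0


class TestGradientAreaSearch:
    def gaussian_sea(self, params, peak=(12, 8), sd=4.0):
        sea = Seascape(
            depth=np.full((20, 20), -2000.0),
            lat=np.full((20, 20), 55.0),
            lon=np.zeros((20, 20)),
        )
        yy, xx = np.mgrid[0:20, 0:20]
        sea.X = 0.2 + 5.0 * np.exp(
            -((yy - peak[0]) ** 2 + (xx - peak[1]) ** 2) / (2 * sd**2)
        )
        sea.SST[:] = 12.0
        sea.p_photo[:] = 0.8
        return sea

    def test_gradient_ascent_improves_cue(self, params):
        sea = self.gaussian_sea(params)
        si = make_adult(params, x=2.0, y=2.0)
        start = profitability(sea, *si.patch, params)
        for _ in range(5):
            gas_daily_step(si, sea, params, random_component=False, speed_noise=False)
        assert profitability(sea, *si.patch, params) >= start

    def test_current_displacement_is_velocity_times_day(self, params):
        sea = self.gaussian_sea(params)
        sea.X[:] = 1.0  # flat cue: directed step from persistent heading only
        results = {}
        for u in (0.0, 0.1):
            sea.U[:] = u
            si = make_adult(params, x=10.0, y=5.0)
            si.heading = (0.0, 1.0)
            si.prev_profit = -1.0
            gas_daily_step(si, sea, params, random_component=False, speed_noise=False)
            results[u] = si.x
        # 0.1 km/h for 24 h = 2.4 km = 0.04 patches of 60 km
        assert results[0.1] - results[0.0] == pytest.approx(2.4 / 60.0)

    def test_random_component_never_southward(self, params):
        sea = self.gaussian_sea(params)
        sea.X[:] = 1.0
        si = make_adult(params, x=10.0, y=10.0)
        for _ in range(50):
            si.x, si.y = 10.0, 10.0  # re-centre to keep both moves in-grid
            y_before = si.y
            heading_move = si.heading[1] * v_min(si.L, params) * 12 / 60
            gas_daily_step(si, sea, params, speed_noise=False)
            # subtracting the directed (northward-heading) half-day leaves
            # the random half-day, which must never point south
            assert si.y - y_before - heading_move >= -1e-9

    def test_cold_patch_reverses_random_heading(self, params):
        sea = self.gaussian_sea(params)
        sea.X[:] = 1.0
        sea.SST[11:, :] = 3.0  # everything north of row 10 is intolerable
        si = make_adult(params, x=10.0, y=10.0)
        si.heading = (1.0, 0.0)
        for _ in range(40):
            gas_daily_step(si, sea, params, speed_noise=False)
            assert sea.SST[si.patch] >= params.SST_lim

    def test_current_into_cold_rescued_to_nearest_suitable(self, params):
        sea = self.gaussian_sea(params)
        sea.X[:] = 1.0
        sea.SST[:, 11:] = 3.0
        sea.U[:] = 2.0  # strong eastward current into the cold half
        si = make_adult(params, x=10.4, y=10.0)
        si.heading = (0.0, 1.0)
        gas_daily_step(si, sea, params, random_component=False, speed_noise=False)
        assert sea.SST[si.patch] >= params.SST_lim

    def test_never_ends_on_land(self, params):
        sea = self.gaussian_sea(params)
        sea.depth[:, 15:] = 100.0
        sea.ocean = sea.depth < 0
        si = make_adult(params, x=13.0, y=10.0)
        for _ in range(30):
            gas_daily_step(si, sea, params)
            assert sea.ocean[si.patch]


class TestRandomWalk:
    def test_single_patch_area_stays_put(self, params, open_sea):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = True
        si = make_adult(params, x=5.0, y=5.0)
        random_walk_in_area(si, open_sea, mask, params)
        assert si.patch == (5, 5)

    def test_occupancy_approximately_uniform(self, params, open_sea):
        mask = np.zeros((20, 20), dtype=bool)
        mask[8:13, 8:13] = True  # symmetric 5x5 area
        si = make_adult(params, x=10.0, y=10.0, L=40.0)
        counts = np.zeros((20, 20))
        for _ in range(10_000):
            si.x, si.y = 10.0, 10.0  # re-centre so every cell is reachable
            random_walk_in_area(si, open_sea, mask, params)
            counts[si.patch] += 1
        observed = counts[mask]
        chi2 = ((observed - observed.mean()) ** 2 / observed.mean()).sum()
        crit = stats.chi2.ppf(0.99, df=observed.size - 1)
        assert chi2 < crit

    def test_never_leaves_area(self, params, open_sea):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:6, 0:6] = True
        si = make_adult(params, x=2.0, y=2.0)
        for _ in range(200):
            random_walk_in_area(si, open_sea, mask, params)
            assert mask[si.patch]


class TestSpawningMove:
    def band_sea(self, params):
        sea = Seascape(
            depth=np.full((15, 15), -300.0),
            lat=np.full((15, 15), 50.0),
            lon=np.zeros((15, 15)),
        )
        sea.SST[:] = 16.0
        return sea

    def test_moves_to_nearest_band_to_the_north(self, params):
        sea = self.band_sea(params)
        sea.SST[8, :] = 12.0  # a 12 degC band three rows north
        si = make_adult(params, x=7.0, y=5.0)
        spawning_move(si, sea, params)
        assert si.patch == (8, 7)

    def test_no_northward_band_falls_back_to_neighbour(self, params):
        sea = self.band_sea(params)
        sea.SST[5, 8] = 12.0  # in-window patch beside, not north
        si = make_adult(params, x=7.0, y=5.0)
        spawning_move(si, sea, params)
        assert si.patch == (5, 8)

    def test_no_window_anywhere_stays(self, params):
        sea = self.band_sea(params)
        si = make_adult(params, x=7.0, y=5.0)
        spawning_move(si, sea, params)
        assert si.patch == (5, 7)
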