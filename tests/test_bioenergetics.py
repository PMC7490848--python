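import math

import pytest
from hypothesis import given, settings, strategies as st

from scomber.bioenergetics import (
    EnergyLedger,
    allocate_reproduction,
    amr,
    arrhenius,
    batch_energy,
    develop_egg,
    grow,
    growth_increment,
    ingestion,
    max_growth,
    potential_fecundity,
    reserves_update,
    select_prey,
    smr,
    spawn_batch,
    step_energy_budget,
)
from scomber.population import (
    Stage,
    length_from_structural_mass,
    make_si_rng,
    structural_mass,
)

from conftest import make_adult


class TestArrhenius:
    def test_identity_at_reference_temperature(self, params):
        assert arrhenius(params.T_ref, params) == 1.0

    def test_ten_degrees_roughly_doubles(self, params):
        assert arrhenius(293.15, params) == pytest.approx(2.011, abs=0.005)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(270.0, 305.0), st.floats(0.1, 5.0))
    def test_strictly_increasing(self, params, T, dT):
        assert arrhenius(T + dT, params) > arrhenius(T, params)


class TestIngestion:
    def test_half_saturation(self, params):
        # X = h, no competitors, reference temperature, unit mass
        ir = ingestion(1.0, params.h, 0.0, params.T_ref, params)
        assert ir == pytest.approx(0.5 * params.C_max)

    def test_saturates_at_maximum_consumption(self, params):
        ir = ingestion(300.0, 1e9, 0.0, params.T_ref, params)
        assert ir == pytest.approx(params.C_max * 300.0 ** (2 / 3), rel=1e-6)

    def test_printed_worked_value(self, params):
        ir = ingestion(300.0, 2 * params.h, 0.0, params.T_ref, params)
        assert ir == pytest.approx(20.6, abs=0.05)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(0.1, 10.0), st.floats(0.0, 1e11), st.floats(1e10, 1e11))
    def test_monotone_in_food_and_density(self, params, X, D, dD):
        base = ingestion(100.0, X, D, params.T_ref, params)
        assert ingestion(100.0, X + 1.0, D, params.T_ref, params) >= base
        assert ingestion(100.0, X, D + dD, params.T_ref, params) <= base


class TestPreySelection:
    def eggs(self, params, n, patch=(5, 5)):
        out = []
        for i in range(n):
            e = make_adult(params, sid=100 + i, x=float(patch[1]), y=float(patch[0]))
            e.stage = Stage.EGG
            e.L = 0.1
            out.append(e)
        return out

    def test_no_cohabitants_gives_none(self, params):
        si = make_adult(params)
        assert select_prey(si, [], params) is None

    def test_choice_is_seeded_uniform(self, params):
        cands = self.eggs(params, 2)
        si1 = make_adult(params, sid=1, seed=42)
        si2 = make_adult(params, sid=1, seed=42)
        assert select_prey(si1, cands, params) is select_prey(si2, cands, params)

    def test_three_times_smaller_is_ineligible(self, params):
        si = make_adult(params, L=0.9)
        prey = self.eggs(params, 1)[0]
        prey.L = 0.3  # exactly 3x smaller: below the 3.5x requirement
        assert select_prey(si, [prey], params) is None

    def test_absolute_length_cutoff(self, params):
        si = make_adult(params, L=30.0)
        prey = self.eggs(params, 1)[0]
        prey.L = 0.4  # > 0.33 cm cutoff even though 75x smaller
        assert select_prey(si, [prey], params) is None

    def test_other_patch_excluded(self, params):
        si = make_adult(params, x=1.0, y=1.0)
        assert select_prey(si, self.eggs(params, 3), params) is None


class TestMetabolicRates:
    def test_smr_printed_value(self, params):
        assert smr(300.0, 283.15, params) == pytest.approx(4.12, abs=0.01)

    def test_smr_power_law(self, params):
        assert smr(600.0, 283.15, params) / smr(300.0, 283.15, params) == (
            pytest.approx(2**0.75)
        )

    def test_smr_monotone_in_temperature(self, params):
        assert smr(300.0, 284.0, params) > smr(300.0, 283.0, params)

    def test_amr_printed_value(self, params):
        assert amr(300.0, 1.85, 283.15, params) == pytest.approx(15.0, abs=0.05)

    def test_amr_zero_speed(self, params):
        assert amr(300.0, 0.0, 283.15, params) == 0.0

    def test_amr_linear_in_speed(self, params):
        assert amr(300.0, 2.0, 283.15, params) == pytest.approx(
            2 * amr(300.0, 1.0, 283.15, params)
        )

    def test_amr_negative_speed_rejected(self, params):
        with pytest.raises(ValueError):
            amr(300.0, -1.0, 283.15, params)


class TestGrowth:
    def test_zero_at_asymptote(self, params):
        assert max_growth(params.L_inf, 400, params.T_ref, params) == 0.0

    def test_zero_at_first_season_ceiling(self, params):
        assert max_growth(params.L_1, 100, params.T_ref, params) == 0.0

    def test_von_bertalanffy_rate_worked_value(self, params):
        # juvenile of 25 cm at the reference temperature
        rate = max_growth(25.0, 400, params.T_ref, params)
        assert rate == pytest.approx(8.6e-4 * (42.4 - 25.0), rel=1e-6)

    def test_adult_rate_doubled_only_when_feeding(self, params):
        juv = max_growth(30.0, 2000, params.T_ref, params, adult=False)
        ad = max_growth(30.0, 2000, params.T_ref, params, adult=True)
        fasting = max_growth(30.0, 2000, params.T_ref, params, adult=True, feeding=False)
        assert ad == pytest.approx(2 * juv)
        assert fasting == 0.0

    def test_increment_integrates_gompertz_exactly(self, params):
        L0, t = 1.0, 0.0
        L = L0
        for step in range(40):
            L += growth_increment(L, step * 5, params.T_ref, 5, params)
        expect = params.L_1 * math.exp(
            -math.log(params.L_1 / L0) * math.exp(-params.k_1 * 200)
        )
        assert L == pytest.approx(expect, rel=1e-12)

    def test_grow_with_zero_energy_is_no_op(self, params):
        si = make_adult(params, L=25.0)
        L_before = si.L
        assert grow(si, 0.1, 0.0, params) == 0.0
        assert si.L == L_before

    def test_grow_full_energy_realizes_full_increment(self, params):
        si = make_adult(params, L=25.0)
        cost = grow(si, 0.1, 1e9, params)
        assert si.L == pytest.approx(25.1)
        dM = structural_mass(25.1, params) - structural_mass(25.0, params)
        assert cost == pytest.approx(dM * (params.E_flesh + params.E_sf))

    def test_grow_half_energy_halves_mass_gain(self, params):
        si = make_adult(params, L=25.0)
        m0 = si.M_struct
        dM_full = structural_mass(25.1, params) - m0
        full_cost = dM_full * (params.E_flesh + params.E_sf)
        grow(si, 0.1, full_cost / 2, params)
        assert si.M_struct - m0 == pytest.approx(dM_full / 2)
        assert si.L == pytest.approx(
            length_from_structural_mass(m0 + dM_full / 2, params)
        )


class TestReserves:
    def test_surplus_pays_synthesis_levy(self, params):
        si = make_adult(params, L=30.0)
        si.energy_reserve = 0.0
        stored, cost, discarded, unmet = reserves_update(si, 53.0, params)
        assert stored == pytest.approx(53.0 * 39.3 / (39.3 + 14.7))  # 38.57 kJ
        assert cost == pytest.approx(53.0 * 14.7 / 54.0)
        assert discarded == pytest.approx(0.0, abs=1e-12)
        assert si.energy_reserve == pytest.approx(stored)

    def test_full_deficit_empties_store(self, params):
        si = make_adult(params, L=30.0)
        r = si.energy_reserve
        delta, _, _, unmet = reserves_update(si, -r, params)
        assert si.energy_reserve == 0.0
        assert delta == -r and unmet == 0.0

    def test_deficit_beyond_store_reported_unmet(self, params):
        si = make_adult(params, L=30.0)
        r = si.energy_reserve
        _, _, _, unmet = reserves_update(si, -(r + 10.0), params)
        assert unmet == pytest.approx(10.0)

    def test_cap_rejects_further_surplus(self, params):
        si = make_adult(params, L=30.0)
        si.energy_reserve = si.reserve_cap(params)
        stored, cost, discarded, _ = reserves_update(si, 100.0, params)
        assert stored == 0.0 and cost == 0.0
        assert discarded == pytest.approx(100.0)
        assert si.energy_reserve == si.reserve_cap(params)


class TestReproduction:
    def test_potential_fecundity_worked_value(self, params):
        assert potential_fecundity(30.0, params) == pytest.approx(2.543e5, rel=1e-3)

    def test_fecundity_increasing_in_length(self, params):
        assert potential_fecundity(35.0, params) > potential_fecundity(30.0, params)

    def run_season(self, params, energy_fraction):
        """Provision and spawn all batches with a fraction of full energy."""
        si = make_adult(params, L=30.0)
        si.f_p = potential_fecundity(si.L, params)
        si.spawning = True
        b_max = batch_energy(si.f_p, params)
        for batch in range(params.n_b):
            for day in range(int(params.b_int)):
                allocate_reproduction(
                    si, energy_fraction * b_max / params.b_int, 1.0, params
                )
            spawn_batch(si, params)
        return si

    def test_full_energy_gives_full_fecundity(self, params):
        si = self.run_season(params, 1.0)
        assert si.eggs_spawned == pytest.approx(si.f_p, rel=1e-9)
        assert si.f_r == pytest.approx(1.0)
        assert not si.spawning and si.batches == params.n_b

    def test_zero_energy_gives_zero_fecundity(self, params):
        si = self.run_season(params, 0.0)
        assert si.eggs_spawned == 0.0 and si.f_r == 0.0

    def test_half_energy_gives_half_fecundity(self, params):
        si = self.run_season(params, 0.5)
        assert si.f_r == pytest.approx(0.5)

    def test_gonads_reset_on_spawn(self, params):
        si = make_adult(params, L=30.0)
        si.f_p = potential_fecundity(si.L, params)
        si.spawning = True
        allocate_reproduction(si, 100.0, 1.0, params)
        assert si.M_gon > 0
        spawn_batch(si, params)
        assert si.M_gon == 0.0

    def test_male_spawns_no_eggs(self, params):
        si = make_adult(params, L=30.0)
        si.gender = "m"
        si.f_p = potential_fecundity(si.L, params)
        si.spawning = True
        allocate_reproduction(si, 100.0, 1.0, params)
        assert spawn_batch(si, params) == 0.0


def test_develop_egg_advances_and_hatches(params):
    si = make_adult(params)
    si.stage = Stage.EGG
    si.development = 0.0
    develop_egg(si, 5.0)
    assert si.development == 5.0


class TestBudgetLedger:
    def test_ledger_closes_for_feeding_adult(self, params):
        si = make_adult(params, L=30.0)
        led = step_energy_budget(si, X=2.0, sst_C=12.0, density=1e9, p=params)
        assert abs(led.residual()) < 1e-9
        assert led.assimilated == pytest.approx(params.A_e * led.intake)

    def test_ledger_closes_under_starvation(self, params):
        si = make_adult(params, L=30.0)
        si.energy_reserve = 1.0
        si.feeding = False
        led = step_energy_budget(si, X=0.0, sst_C=12.0, density=0.0, p=params)
        assert abs(led.residual()) < 1e-9
        assert led.unmet > 0
        assert si.starving

    def test_reserve_delta_matches_state_change(self, params):
        si = make_adult(params, L=30.0)
        before = si.energy_reserve
        led = step_energy_budget(si, X=5.0, sst_C=12.0, density=0.0, p=params)
        assert si.energy_reserve - before == pytest.approx(led.reserve_delta)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.0, 10.0),
        st.floats(8.0, 18.0),
        st.floats(0.0, 1e11),
        st.floats(5.0, 41.0),
        st.booleans(),
    )
    def test_ledger_closure_is_universal(self, params, X, sst, D, L, active):
        si = make_adult(params, L=L)
        si.stage = Stage.ADULT if L >= params.L_mat else Stage.JUVENILE
        led = step_energy_budget(
            si, X=X, sst_C=sst, density=D, p=params,
            active=active, active_speed=2.0,
        )
        assert abs(led.residual()) < 1e-9

    def test_no_negative_masses_or_overfull_reserves(self, params):
        si = make_adult(params, L=20.0)
        si.stage = Stage.JUVENILE
        for _ in range(200):
            step_energy_budget(si, X=50.0, sst_C=14.0, density=0.0, p=params)
            assert si.M_struct > 0
            assert 0 <= si.energy_reserve <= si.reserve_cap(params) * (1 + 1e-9)

    def test_fasting_spawner_funds_gonads_from_reserves(self, params):
        si = make_adult(params, L=30.0)
        si.feeding = False
        si.spawning = True
        si.f_p = potential_fecundity(si.L, params)
        r0 = si.energy_reserve
        led = step_energy_budget(si, X=2.0, sst_C=11.0, density=0.0, p=params)
        assert led.intake == 0.0
        assert led.reproduction_cost > 0
        assert si.energy_reserve < r0
        assert abs(led.residual()) < 1e-9
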