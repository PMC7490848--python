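"""Run lifecycle: the 12-phase per-time-step process order, the annual
event calendar, spin-up, and output extraction.

Each 5-day step executes, in order: forcing refresh (10-day composites,
month-start photoperiod/currents, year-start F-at-age); mortality (fishing,
starvation, background); movement; energy budgets (excluding reproduction);
stage progression (with the February 1st maturation census); the March 1st
fecundity calculation; the spawning module (batch provisioning, spawning at
inter-batch intervals, northward spawning movement); entry of new egg SIs;
ageing; and state recording.  The order in which SIs carry out a process is
randomized every step; state variables update immediately.

The calendar ignores leap days: 365-day years, 73 steps, with dated events
bound to the step that contains them.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import dates as cal
from .parameters import ParameterSet, load_parameters, scenario_F
from .seascape import (
    Forcing,
    Seascape,
    build_grid,
    generate_synthetic_forcing,
    update_forcing,
)
from .population import (
    Stage,
    SuperIndividual,
    initialize_population,
    population_to_frame,
    spinup_recruit,
)
from .movement import (
    gas_daily_step,
    migration_step,
    random_walk_in_area,
    spawning_move,
    v_min,
)
from .bioenergetics import (
    develop_egg,
    growth_increment,
    potential_fecundity,
    select_prey,
    smr,
    spawn_batch,
    step_energy_budget,
)
from .population import structural_mass
from .demography import (
    FishingSchedule,
    apply_mortality,
    background_mortality,
    predation_mortality,
    recruit_emergent,
    recruit_ricker,
    starvation_check,
)

__all__ = ["World", "RunOutputs", "run", "SchedulerError"]

logger = logging.getLogger("scomber")

_GRAMS_PER_TONNE = 1e6


class SchedulerError(ValueError):
    pass


@dataclass
class RunOutputs:
    """Population metrics extracted on their census dates, keyed by year."""

    ssb_summer: dict = field(default_factory=dict)        # Aug 1, tonnes
    ssb_spawning: dict = field(default_factory=dict)      # May 1, tonnes
    egg_production: dict = field(default_factory=dict)    # Jun 1, eggs
    recruitment: dict = field(default_factory=dict)       # Dec 31, individuals
    maturity_ogive: dict = field(default_factory=dict)    # Feb 10, age -> prop
    adult_age_dist: dict = field(default_factory=dict)    # Aug 1, age -> prop
    weight_at_age_summer: dict = field(default_factory=dict)    # Aug 1, g
    weight_at_age_spawning: dict = field(default_factory=dict)  # May 1, g
    weight_36cm: dict = field(default_factory=dict)       # (year, month) -> g
    juv_lengths_q1: dict = field(default_factory=dict)    # Mar 16
    juv_lengths_q4: dict = field(default_factory=dict)    # Nov 23
    presence: dict = field(default_factory=dict)          # Jul/Aug mean
    density: dict = field(default_factory=dict)           # Jul/Aug mean, g patch-1
    n_si: dict = field(default_factory=dict)              # SI count per year end
    spinup_recruit_lengths: list = field(default_factory=list)
    max_ledger_residual: float = 0.0
    cold_settlement_violations: int = 0    # adults ending a summer step < 7 degC
    removals: dict = field(default_factory=lambda: {
        "starvation": 0, "abundance": 0, "max_age": 0,
    })
    trajectories: list = field(default_factory=list)
    final_population: pd.DataFrame | None = None

    def ssb_series(self, which: str = "spawning") -> pd.Series:
        src = self.ssb_spawning if which == "spawning" else self.ssb_summer
        return pd.Series(src, name=f"ssb_{which}").sort_index()

    def weight_at_age_frame(self, which: str = "spawning") -> pd.DataFrame:
        src = (
            self.weight_at_age_spawning
            if which == "spawning"
            else self.weight_at_age_summer
        )
        return pd.DataFrame(src).T.sort_index()

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.ssb_series("spawning").to_csv(out / "ssb_spawning.csv")
        self.ssb_series("summer").to_csv(out / "ssb_summer.csv")
        pd.Series(self.egg_production, name="eggs").sort_index().to_csv(
            out / "egg_production.csv"
        )
        pd.Series(self.recruitment, name="recruits").sort_index().to_csv(
            out / "recruitment.csv"
        )
        for which in ("spawning", "summer"):
            self.weight_at_age_frame(which).to_csv(out / f"weight_at_age_{which}.csv")
        if self.presence:
            import xarray as xr

            years = sorted(self.presence)
            ds = xr.Dataset(
                {
                    "presence": (
                        ("year", "y", "x"),
                        np.stack([self.presence[y] for y in years]),
                    ),
                    "density": (
                        ("year", "y", "x"),
                        np.stack([self.density[y] for y in years]),
                    ),
                },
                coords={"year": years},
            )
            ds.to_netcdf(out / "summer_maps.nc", engine="scipy")
        if self.trajectories:
            pd.DataFrame(
                self.trajectories,
                columns=["year", "doy", "si_id", "x", "y", "mode"],
            ).to_csv(out / "trajectories.csv", index=False)
        if self.final_population is not None:
            self.final_population.to_csv(out / "final_population.csv", index=False)


class World:
    """Mutable simulation state plus the per-step process order."""

    def __init__(
        self,
        params: ParameterSet,
        sea: Seascape,
        forcing: Forcing,
        fishing: FishingSchedule,
        pop: list[SuperIndividual],
        master_seed: int,
        start_year: int,
        spinup_years: int = 10,
        spinup_recruitment: float | Mapping[int, float] = 1e9,
        recruitment_mode: str = "emergent",
        ricker: Mapping | None = None,
        movement_enabled: bool = True,
        feeding_enabled: bool = True,
        bioenergetics_enabled: bool = True,
        gas_random_component: bool = True,
        gas_speed_noise: bool = True,
        mortality_override: float | None = None,
        record_trajectories: bool = False,
    ) -> None:
        self.p = params
        self.sea = sea
        self.forcing = forcing
        self.fishing = fishing
        self.pop = pop
        self.master_seed = int(master_seed) & 0x7FFFFFFF
        self.shuffle_rng = random.Random(self.master_seed ^ 0x5EA5CAFE)
        self.start_year = start_year
        self.year = start_year
        self.step_in_year = 0
        self.spinup_years = spinup_years
        self.spinup_recruitment = spinup_recruitment
        self.recruitment_mode = recruitment_mode
        self.ricker = ricker
        self.movement_enabled = movement_enabled
        self.feeding_enabled = feeding_enabled
        self.bioenergetics_enabled = bioenergetics_enabled
        self.gas_random_component = gas_random_component
        self.gas_speed_noise = gas_speed_noise
        self.mortality_override = mortality_override
        self.record_trajectories = record_trajectories
        self.next_id = (max((s.id for s in pop), default=-1)) + 1
        self.outputs = RunOutputs()
        # spawning-season state
        self.season_eggs = 0.0
        self.cohort_plan = [
            len(a)
            for a in np.array_split(np.arange(params.n_cohort), params.n_b)
        ]
        # July/August map accumulators
        self._summer_maps: list[np.ndarray] = []
        self._summer_presence: list[np.ndarray] = []

    # ------------------------------------------------------------------
    @property
    def in_spinup(self) -> bool:
        return self.year < self.start_year + self.spinup_years

    def _doy0(self) -> int:
        return self.step_in_year * cal.STEP_DAYS + 1

    def _event_in_step(self, doy: int) -> bool:
        d0 = self._doy0()
        return d0 <= doy <= d0 + cal.STEP_DAYS - 1

    def _take_id(self) -> int:
        i = self.next_id
        self.next_id += 1
        return i

    def _shuffled(self) -> list[SuperIndividual]:
        order = list(self.pop)
        self.shuffle_rng.shuffle(order)
        return order

    def _recompute_density(self) -> None:
        D = np.zeros((self.sea.ny, self.sea.nx))
        p = self.p
        for si in self.pop:
            D[si.patch] += si.abundance * si.total_mass(p)
        self.sea.D = D

    def _patch_index(self) -> dict[tuple[int, int], list[SuperIndividual]]:
        idx: dict[tuple[int, int], list[SuperIndividual]] = {}
        for si in self.pop:
            idx.setdefault(si.patch, []).append(si)
        return idx

    # ------------------------------------------------------------------
    # the 12-phase step
    # ------------------------------------------------------------------
    def step(self) -> None:
        p = self.p
        sea = self.sea
        d0 = self._doy0()
        days = list(cal.step_days_covered(self.step_in_year))

        # (1)-(3) forcing refresh: 10-day composites, month starts, year
        # starts (annual F-at-age is resolved per-step through the schedule)
        for d in days:
            update_forcing(sea, self.forcing, self.year, d)

        # calendar-triggered migration/fasting flags
        self._fire_calendar_events()

        # (4) mortality: fishing, starvation, background
        if self.mortality_override is None:
            f_day_by_age = [
                self.fishing.step_F(self.year, d0, a) / p.step_days
                for a in range(16)
            ]
        for si in self._shuffled():
            if not si.alive:
                continue
            starvation_check(si)
            if not si.alive:
                self.outputs.removals["starvation"] += 1
                continue
            if self.mortality_override is not None:
                m_back, f_day = self.mortality_override, 0.0
            else:
                m_back = background_mortality(si, p)
                f_day = f_day_by_age[min(int(si.age_years), 15)]
            apply_mortality(si, m_back, f_day, p.step_days)
            if not si.alive:
                self.outputs.removals["abundance"] += 1
        self.pop = [si for si in self.pop if si.alive]

        # (5) movement
        speeds: dict[int, tuple[bool, float]] = {}
        if self.movement_enabled:
            self._recompute_density()  # GAS cue needs up-to-date density
            for si in self._shuffled():
                speeds[si.id] = self._move(si)

        # (6) energy budgets (reproduction allocation included for spawning
        # adults; batch release comes in phase 9)
        if self.bioenergetics_enabled:
            self._recompute_density()
            index = self._patch_index()
            for si in self._shuffled():
                if not si.alive:
                    continue
                if si.stage == Stage.EGG:
                    develop_egg(si, p.step_days)
                    continue
                if si.stage == Stage.YOLK_SAC:
                    # yolk-fuelled: maximal growth at no energetic cost
                    sst_K = sea.SST[si.patch] + 273.15
                    dL = growth_increment(si.L, si.age_days, sst_K, p.step_days, p)
                    si.L += dL
                    si.M_struct = structural_mass(si.L, p)
                    continue
                active, speed = speeds.get(si.id, (False, 0.0))
                yx = si.patch
                prey = (
                    select_prey(si, index.get(yx, ()), p)
                    if si.feeding and self.feeding_enabled
                    else None
                )
                reserve_floor = 0.0
                if si.spawning and not si.feeding:
                    # projected fasting maintenance until feeding resumes
                    fast_days = max(cal.DOY_FEED_MIGRATION - self._doy0(), 0)
                    reserve_floor = (
                        smr(si.total_mass(p), sea.SST[yx] + 273.15, p)
                        * fast_days
                    )
                led = step_energy_budget(
                    si,
                    X=sea.X[yx],
                    sst_C=sea.SST[yx],
                    density=sea.D[yx],
                    p=p,
                    active=active,
                    active_speed=speed,
                    prey=prey,
                    feeding_enabled=self.feeding_enabled,
                    reserve_floor=reserve_floor,
                )
                if prey is not None and led.intake_g > 0:
                    predation_mortality(prey, si, led.intake_g, p)
                res = abs(led.residual())
                if res > self.outputs.max_ledger_residual:
                    self.outputs.max_ledger_residual = res

        # (7) stage progression (maturation only on the Feb 1 census)
        from .population import transform_stage

        mat_doy = (
            cal.DOY_MATURATION
            if self._event_in_step(cal.DOY_MATURATION)
            else d0
        )
        for si in self.pop:
            transform_stage(si, mat_doy, p, sea)

        # (8) potential fecundity at the start of the spawning period
        if self._event_in_step(cal.DOY_SPAWN_START):
            self._begin_spawning_season()

        # (9) spawning module: batch release + northward spawning movement
        self._spawning_module()

        # (10) new egg SIs entered inside the spawning module (per batch)

        # (11) ageing
        for si in self.pop:
            si.age_days += p.step_days

        # (12) state recording
        self._record(d0)

        self.step_in_year += 1
        if self.step_in_year == cal.STEPS_PER_YEAR:
            self._year_end()
            self.step_in_year = 0
            self.year += 1

    # ------------------------------------------------------------------
    def _fire_calendar_events(self) -> None:
        p = self.p
        if self._event_in_step(cal.DOY_SPAWN_MIGRATION):
            for si in self.pop:
                if si.stage == Stage.ADULT:
                    si.migrating = True
                    si.migration_mode = "spawning"
                    si.stop_distance = 0
        if self._event_in_step(cal.DOY_FEED_MIGRATION):
            for si in self.pop:
                if si.stage == Stage.ADULT:
                    si.spawning = False
                    si.feeding = True   # the fast ends after spawning
                    si.migrating = True
                    si.migration_mode = "feeding"
                    si.stop_distance = si.rng.randint(0, p.stop_distance_max)
                    si.prev_profit = -1.0
        if self._event_in_step(cal.DOY_OVERWINTER_MIGRATION):
            for si in self.pop:
                if si.stage == Stage.ADULT:
                    si.migrating = True
                    si.migration_mode = "overwintering"
                    si.stop_distance = 0
        if self._event_in_step(cal.DOY_FAST_START):
            for si in self.pop:
                if si.stage == Stage.ADULT:
                    si.feeding = False

    def _move(self, si: SuperIndividual) -> tuple[bool, float]:
        """Move one SI; returns (metabolically active, speed km h-1)."""
        p, sea = self.p, self.sea
        if si.stage in (Stage.EGG, Stage.YOLK_SAC, Stage.LARVA):
            return (False, 0.0)  # passive early stages; drift not modelled
        if si.stage == Stage.JUVENILE:
            random_walk_in_area(si, sea, sea.narea, p)
            return (False, 0.0)
        # adults
        if si.migrating:
            mode = si.migration_mode
            R = sea.spawn_dist if mode == "spawning" else sea.feed_dist
            constrain = mode in ("spawning", "feeding")
            migration_step(si, sea, R, p, constrain_shelf=constrain)
            return (True, v_min(si.L, p))
        d0 = self._doy0()
        in_feeding_season = cal.DOY_FEED_MIGRATION <= d0 < cal.DOY_OVERWINTER_MIGRATION
        if in_feeding_season and si.feeding:
            swim = 0.0
            for _ in range(p.step_days):
                swim += gas_daily_step(
                    si,
                    sea,
                    p,
                    random_component=self.gas_random_component,
                    speed_noise=self.gas_speed_noise,
                )
            if cal.is_summer(d0) and sea.SST[si.patch] < p.SST_lim:
                self.outputs.cold_settlement_violations += 1
            if self.record_trajectories:
                self.outputs.trajectories.append(
                    (self.year, d0, si.id, si.x, si.y, "gas")
                )
            return (True, swim / (24.0 * p.step_days))
        if d0 >= cal.DOY_OVERWINTER_MIGRATION or d0 < cal.DOY_SPAWN_MIGRATION:
            random_walk_in_area(si, sea, sea.owarea, p)
        elif si.spawning:
            pass  # spawning movement happens after each batch (phase 9)
        # waiting at the spawning grounds before March 1st: hold position
        return (False, 0.0)

    def _begin_spawning_season(self) -> None:
        p = self.p
        self.season_eggs = 0.0
        self.season_day0 = (self.year, self._doy0())
        for si in self.pop:
            if si.stage == Stage.ADULT:
                # potential fecundity is a female trait; males mirror the
                # allocation so that reproductive investment is equal
                si.f_p = potential_fecundity(si.L, p)
                si.spawning = True
                si.batches = 0
                si.eggs_spawned = 0.0
                si.M_gon = 0.0

    def _spawning_module(self) -> None:
        p = self.p
        d0 = self._doy0()
        season_elapsed = d0 + cal.STEP_DAYS - cal.DOY_SPAWN_START
        if not (0 < season_elapsed <= p.season_length + cal.STEP_DAYS):
            return
        spawners = [si for si in self.pop if si.spawning and si.stage == Stage.ADULT]
        if not spawners:
            return
        batch_no = None
        batch_eggs = 0.0
        locations: list[tuple[float, float]] = []
        for si in self._shuffled():
            if not (si.spawning and si.stage == Stage.ADULT):
                continue
            due = int(season_elapsed // p.b_int)
            while si.batches < min(due, p.n_b):
                batch_no = si.batches + 1
                eggs = spawn_batch(si, p)
                if eggs > 0:
                    batch_eggs += eggs * si.abundance
                    locations.append((si.y, si.x))
                if self.movement_enabled:
                    spawning_move(si, self.sea, p)
        self.season_eggs += batch_eggs
        # phase (10): each batch funds an equal share of the year's cohort
        if (
            batch_no is not None
            and batch_eggs > 0
            and not self.in_spinup
            and self.recruitment_mode == "emergent"
        ):
            n_new = self.cohort_plan[min(batch_no, p.n_b) - 1]
            if n_new > 0:
                id_start = self.next_id
                new = recruit_emergent(
                    batch_eggs,
                    locations,
                    n_new,
                    p,
                    self.master_seed,
                    id_start,
                )
                self.next_id = id_start + len(new)
                self.pop.extend(new)

    # ------------------------------------------------------------------
    def _record(self, d0: int) -> None:
        p = self.p
        y = self.year
        out = self.outputs
        adults = [s for s in self.pop if s.stage == Stage.ADULT]
        if self._event_in_step(cal.DOY_FEED_MIGRATION):  # May 1
            out.ssb_spawning[y] = (
                sum(s.total_mass(p) * s.abundance for s in adults) / _GRAMS_PER_TONNE
            )
            out.weight_at_age_spawning[y] = self._weight_at_age(adults)
        if self._event_in_step(cal.DOY_SUMMER_CENSUS):  # Aug 1
            out.ssb_summer[y] = (
                sum(s.total_mass(p) * s.abundance for s in adults) / _GRAMS_PER_TONNE
            )
            out.weight_at_age_summer[y] = self._weight_at_age(adults)
            total_ab = sum(s.abundance for s in adults)
            if total_ab > 0:
                dist: dict[int, float] = {}
                for s in adults:
                    dist[int(s.age_years)] = (
                        dist.get(int(s.age_years), 0.0) + s.abundance / total_ab
                    )
                out.adult_age_dist[y] = dist
        if self._event_in_step(cal.DOY_EGG_CENSUS):  # Jun 1
            out.egg_production[y] = self.season_eggs
        if self._event_in_step(cal.DOY_OGIVE_CENSUS):  # Feb 10
            out.maturity_ogive[y] = self._maturity_ogive()
        if self._event_in_step(cal.DOY_Q1_JUV_CENSUS):
            out.juv_lengths_q1[y] = self._juvenile_lengths()
        if self._event_in_step(cal.DOY_Q4_JUV_CENSUS):
            out.juv_lengths_q4[y] = self._juvenile_lengths()
        # monthly 36-cm class weight: first step of each month
        month = cal.month_of_doy(d0)
        if (y, month) not in out.weight_36cm:
            grp = [
                s
                for s in self.pop
                if 35.5 <= s.L < 36.5 and s.stage >= Stage.JUVENILE
            ]
            ab = sum(s.abundance for s in grp)
            if ab > 0:
                out.weight_36cm[(y, month)] = (
                    sum(s.total_mass(p) * s.abundance for s in grp) / ab
                )
        # July/August distribution maps
        if cal.is_summer(d0):
            self._recompute_density()
            self._summer_maps.append(self.sea.D.copy())
            self._summer_presence.append(self.sea.D > 0)

    def _weight_at_age(self, group) -> dict[int, float]:
        p = self.p
        acc: dict[int, list[float]] = {}
        for s in group:
            acc.setdefault(int(s.age_years), [0.0, 0.0])
        for s in group:
            a = int(s.age_years)
            acc[a][0] += s.total_mass(p) * s.abundance
            acc[a][1] += s.abundance
        return {a: m / n for a, (m, n) in acc.items() if n > 0}

    def _maturity_ogive(self) -> dict[int, float]:
        acc: dict[int, list[float]] = {}
        for s in self.pop:
            if s.stage < Stage.JUVENILE:
                continue
            a = int(s.age_years)
            acc.setdefault(a, [0.0, 0.0])
            acc[a][1] += s.abundance
            if s.stage == Stage.ADULT:
                acc[a][0] += s.abundance
        return {a: m / n for a, (m, n) in acc.items() if n > 0}

    def _juvenile_lengths(self) -> list[tuple[float, float]]:
        return [
            (s.L, s.abundance) for s in self.pop if s.stage == Stage.JUVENILE
        ]

    # ------------------------------------------------------------------
    def _year_end(self) -> None:
        p = self.p
        y = self.year
        # recruitment entry on December 31st
        if self.in_spinup:
            rec = self.spinup_recruitment
            if isinstance(rec, Mapping):
                rec = rec.get(y, rec.get(str(y), 0.0))
            new = spinup_recruit(
                float(rec),
                p,
                self.sea,
                self.master_seed,
                y - self.start_year,
                in_spinup=True,
                id_start=self.next_id,
            )
            self.next_id += len(new)
            self.outputs.spinup_recruit_lengths.extend(s.L for s in new)
            self.pop.extend(new)
        elif self.recruitment_mode == "ricker":
            ssb_t = self.outputs.ssb_spawning.get(y, 0.0) * _GRAMS_PER_TONNE
            mask = self.sea.sarea if self.sea.sarea.any() else self.sea.shelf_edge
            mean_sst = float(self.sea.SST[mask].mean())
            recruits = recruit_ricker(ssb_t, mean_sst, self.ricker)
            if recruits > 0:
                new = spinup_recruit(
                    recruits,
                    p,
                    self.sea,
                    self.master_seed,
                    y - self.start_year,
                    in_spinup=True,
                    id_start=self.next_id,
                )
                self.next_id += len(new)
                self.pop.extend(new)
        # December 31st recruitment census: young-of-the-year survivors
        self.outputs.recruitment[y] = sum(
            s.abundance for s in self.pop if s.age_days <= 365.0
        )
        # July/August maps for the year
        if self._summer_maps:
            self.outputs.density[y] = np.mean(self._summer_maps, axis=0)
            self.outputs.presence[y] = np.mean(self._summer_presence, axis=0)
            self._summer_maps.clear()
            self._summer_presence.clear()
        # removal at maximum age balances cohort entry
        survivors = []
        for s in self.pop:
            if not s.alive:
                continue
            if s.age_years >= p.max_age_years:
                self.outputs.removals["max_age"] += 1
                continue
            survivors.append(s)
        self.pop = survivors
        self.outputs.n_si[y] = len(self.pop)
        logger.info(
            "year %d done: %d SIs, SSB(spawn) %.1f t",
            y,
            len(self.pop),
            self.outputs.ssb_spawning.get(y, float("nan")),
        )


# ---------------------------------------------------------------------------
# configuration-driven runs
# ---------------------------------------------------------------------------

def _default_numbers_at_age(n0: float = 1e8, z: float = 0.35) -> dict[int, float]:
    return {a: n0 * float(np.exp(-z * a)) for a in range(15)}


def _default_mean_F(level: float = 0.277) -> dict[int, float]:
    # dome over the fishery's most important ages (4-8)
    out = {}
    for a in range(16):
        if a < 2:
            out[a] = 0.06 * level / 0.277
        elif a < 4:
            out[a] = 0.18 * level / 0.277
        elif a <= 8:
            out[a] = level
        else:
            out[a] = 0.8 * level
    return out


def build_world(config: Mapping | str | None, seed: int = 0) -> World:
    """Assemble a :class:`World` from a configuration document (a mapping
    or YAML text) with sections ``parameters``, ``scenario``, ``grid``,
    ``forcing``, ``initial``, ``fishing``, ``schedule`` and ``outputs``."""
    if isinstance(config, str):
        config = yaml.safe_load(config) or {}
    config = dict(config or {})
    p = load_parameters({"parameters": config.get("parameters", {})})
    sched = dict(config.get("schedule", {}))
    start_year = int(sched.get("start_year", 2000))
    spinup_years = int(sched.get("spinup_years", 10))
    run_years = int(sched.get("run_years", 2))

    sea = build_grid(config.get("grid"))
    fspec = dict(config.get("forcing", {}))
    fspec.setdefault("year0", start_year)
    fspec.setdefault("n_years", spinup_years + run_years)
    forcing_seed = (int(seed) ^ 0x0F0F0F0F) & 0x7FFFFFFF
    forcing = generate_synthetic_forcing(sea, fspec, seed=forcing_seed)
    horizon_end = start_year + spinup_years + run_years - 1
    if not (forcing.covers(start_year) and forcing.covers(horizon_end)):
        raise SchedulerError(
            f"forcing covers {forcing.year0}..{forcing.year0 + forcing.n_years - 1} "
            f"but the run needs {start_year}..{horizon_end}"
        )

    init = config.get("initial", {})
    if isinstance(init, str):
        naa = pd.read_csv(init).set_index("age")["abundance"].to_dict()
    else:
        naa = {
            int(a): float(v)
            for a, v in dict(
                init.get("numbers_at_age", _default_numbers_at_age())
            ).items()
        }

    fish = dict(config.get("fishing", {}))
    mean_F = {
        int(a): float(v)
        for a, v in dict(fish.get("mean_F_at_age", _default_mean_F())).items()
    }
    scenario = str(config.get("scenario", "historical-mean"))
    F = scenario_F(mean_F, scenario)
    mfrac = fish.get(
        "month_fractions",
        [0.13, 0.11, 0.08, 0.03, 0.02, 0.02, 0.03, 0.05, 0.10, 0.15, 0.15, 0.13],
    )
    fishing = FishingSchedule(annual_F=F, month_fractions=mfrac)

    n_si = int(sched.get("n_si", 1050))
    allow_test_scale = bool(sched.get("allow_test_scale", False))
    pop = initialize_population(
        naa,
        n_si,
        p,
        sea,
        master_seed=seed,
        allow_test_scale=allow_test_scale,
    )
    if "n_cohort" not in dict(config.get("parameters", {})):
        # the cohort follows the SI count: n_si multiples of 1050 give
        # n_cohort multiples of 70; reduced test worlds shrink in proportion
        p = p.replace(n_cohort=max(n_si // 15, 1))

    outputs_cfg = dict(config.get("outputs", {}))
    return World(
        params=p,
        sea=sea,
        forcing=forcing,
        fishing=fishing,
        pop=pop,
        master_seed=seed,
        start_year=start_year,
        spinup_years=spinup_years,
        spinup_recruitment=sched.get("spinup_recruitment", naa[0]),
        recruitment_mode=str(sched.get("recruitment", "emergent")),
        ricker=sched.get("ricker"),
        movement_enabled=bool(sched.get("movement_enabled", True)),
        feeding_enabled=bool(sched.get("feeding_enabled", True)),
        bioenergetics_enabled=bool(sched.get("bioenergetics_enabled", True)),
        gas_random_component=bool(sched.get("gas_random_component", True)),
        gas_speed_noise=bool(sched.get("gas_speed_noise", True)),
        mortality_override=sched.get("mortality_override"),
        record_trajectories=bool(outputs_cfg.get("trajectories", False)),
    )


def run(config: Mapping | str | None, seed: int = 0) -> RunOutputs:
    """Initialize on January 1st, spin up with forced recruitment, then run
    the main phase with emergent (or Ricker) recruitment, extracting every
    census metric on its date."""
    if isinstance(config, str):
        config = yaml.safe_load(config) or {}
    config = dict(config or {})
    world = build_world(config, seed)
    run_years = int(dict(config.get("schedule", {})).get("run_years", 2))
    total_steps = (world.spinup_years + run_years) * cal.STEPS_PER_YEAR
    for _ in range(total_steps):
        world.step()
    world.outputs.final_population = population_to_frame(world.pop, world.p)
    return world.outputs
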