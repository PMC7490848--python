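"""Super-individual state, initialization, spin-up recruits, and
ontogenetic transitions.

A super-individual (SI) is an agent standing for ``abundance`` identical
fish.  Mortality scales the abundance; an SI whose abundance falls below one
is removed.  Stage transitions (egg -> yolk-sac larva -> larva -> juvenile
-> adult) are irreversible and length-triggered, except maturation which is
censused once a year on February 1st.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .seascape import Seascape
from .dates import DOY_MATURATION

__all__ = [
    "Stage",
    "SuperIndividual",
    "initialize_population",
    "spinup_recruit",
    "transform_stage",
    "length_at_age",
    "structural_mass",
    "length_from_structural_mass",
    "population_to_frame",
    "PopulationError",
]

# day of year on which cohorts are nominally hatched, used to convert age in
# whole years to days post-hatch at the January 1st initialization (peak
# spawning falls in late spring)
HATCH_DOY = 152


class PopulationError(ValueError):
    pass


class Stage(IntEnum):
    EGG = 0
    YOLK_SAC = 1
    LARVA = 2
    JUVENILE = 3
    ADULT = 4


def structural_mass(L: float, p: ParameterSet) -> float:
    """Allometric length -> structural wet mass (g)."""
    return p.a_w * L ** p.b_w


def length_from_structural_mass(m_struct: float, p: ParameterSet) -> float:
    return (m_struct / p.a_w) ** (1.0 / p.b_w)


def length_at_age(age_days: float, p: ParameterSet) -> float:
    """von Bertalanffy length-at-age used at initialization."""
    return p.L_inf * (1.0 - math.exp(-p.k * (age_days - p.t_0)))


@dataclass(slots=True)
class SuperIndividual:
    id: int
    abundance: float
    age_days: float
    gender: str                      # 'f' or 'm'
    stage: Stage
    L: float                         # body length, cm
    M_struct: float                  # structural mass, g
    energy_reserve: float            # lipid store, kJ
    x: float                         # continuous position, patch units
    y: float
    rng: random.Random               # private stream; survives removals of
                                     # other SIs without shifting their draws
    M_gon: float = 0.0               # gonad mass, g
    development: float = 0.0         # days developed as egg
    batches: int = 0                 # egg batches spawned this season
    f_p: float = 0.0                 # potential fecundity, eggs
    eggs_spawned: float = 0.0        # realized eggs this season (per female)
    f_r: float = 0.0                 # realized / potential fecundity
    F_applied: float = 0.0           # fishing mortality, day-1
    feeding: bool = True
    migrating: bool = False
    migration_mode: str = ""         # 'spawning' | 'feeding' | 'overwintering'
    stop_distance: int = 0
    spawning: bool = False
    heading: tuple[float, float] = (0.0, 1.0)
    prev_profit: float = -1.0        # profitability sensed the previous day
    A_mat: float = float("nan")      # age (years) at maturation
    L_mat_attained: float = float("nan")
    fed_once: bool = False           # larvae are starvation-exempt until set
    starving: bool = False           # store run down to nothing by a deficit
    alive: bool = True

    # -- derived masses --------------------------------------------------
    def lipid_mass(self, p: ParameterSet) -> float:
        return self.energy_reserve / p.E_lipid

    def total_mass(self, p: ParameterSet) -> float:
        """M = structure + lipid store + gonads (g wet weight)."""
        return self.M_struct + self.lipid_mass(p) + self.M_gon

    def standard_mass(self, p: ParameterSet) -> float:
        return self.M_struct + self.lipid_mass(p)

    def reserve_cap(self, p: ParameterSet) -> float:
        """Maximum lipid store in kJ: E_max is a proportion of structural
        mass, applied literally in mass terms."""
        return p.E_max * self.M_struct * p.E_lipid

    @property
    def age_years(self) -> float:
        return self.age_days / 365.0

    @property
    def patch(self) -> tuple[int, int]:
        # nearest-cell index; positions are non-negative in patch units
        return int(self.y + 0.5), int(self.x + 0.5)


def _place_random(mask: np.ndarray, rng: random.Random) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise PopulationError("cannot place individuals: area mask is empty")
    i = rng.randrange(ys.size)
    return float(ys[i]), float(xs[i])


def make_si_rng(master_seed: int, si_id: int) -> random.Random:
    """Per-SI stream: deaths of other SIs never shift this SI's draws."""
    ss = np.random.SeedSequence(
        entropy=[int(master_seed) & 0x7FFFFFFF, (int(si_id) + 2) & 0x7FFFFFFF]
    )
    return random.Random(int(ss.generate_state(1)[0]))


def initialize_population(
    numbers_at_age: Mapping[int, float],
    n_si: int,
    params: ParameterSet,
    sea: Seascape,
    master_seed: int = 0,
    allow_test_scale: bool = False,
    id_start: int = 0,
) -> list[SuperIndividual]:
    """Apportion assessment numbers-at-age into ``n_si`` super-individuals.

    Fifteen age classes (0..14) each receive ``n_si / 15`` SIs with a 1:1
    gender ratio; lengths come from the von Bertalanffy curve at age,
    energy reserves start at half maximum, adults are placed randomly in the
    overwintering area and juveniles in the nursery area.
    """
    n_ages = 15
    if n_si % 1050 != 0 and not allow_test_scale:
        raise PopulationError(
            f"n_si = {n_si} must be a multiple of 1050 "
            "(70 SIs per cohort x 15 age groups); pass allow_test_scale=True "
            "only for reduced test worlds"
        )
    if n_si % n_ages != 0:
        raise PopulationError(f"n_si = {n_si} not divisible by {n_ages} ages")
    per_class = n_si // n_ages
    missing = sorted(set(range(n_ages)) - {int(a) for a in numbers_at_age})
    if missing:
        raise PopulationError(f"numbers-at-age missing ages: {missing}")
    if any(v <= 0 for v in numbers_at_age.values()):
        raise PopulationError("numbers-at-age must be positive")

    place_rng = make_si_rng(master_seed, -1)
    pop: list[SuperIndividual] = []
    sid = id_start
    for age in range(n_ages):
        n_class = float(numbers_at_age[age])
        age_days = age * 365.0 + (365.0 - HATCH_DOY + 1.0)
        L = length_at_age(age_days, params)
        m_struct = structural_mass(L, params)
        reserve = 0.5 * params.E_max * m_struct * params.E_lipid
        stage = Stage.ADULT if L >= params.L_mat else Stage.JUVENILE
        mask = sea.owarea if stage == Stage.ADULT else sea.narea
        for i in range(per_class):
            y, x = _place_random(mask, place_rng)
            si = SuperIndividual(
                id=sid,
                abundance=n_class / per_class,
                age_days=age_days,
                gender="f" if i % 2 == 0 else "m",
                stage=stage,
                L=L,
                M_struct=m_struct,
                energy_reserve=reserve,
                x=x,
                y=y,
                rng=make_si_rng(master_seed, sid),
            )
            if stage == Stage.ADULT:
                si.A_mat = si.age_years
                si.L_mat_attained = L
                si.feeding = False  # the winter fast is under way on Jan 1
            si.fed_once = True
            pop.append(si)
            sid += 1
    return pop


def spinup_recruit(
    year_abundance: float,
    params: ParameterSet,
    sea: Seascape,
    master_seed: int,
    year_index: int,
    in_spinup: bool,
    id_start: int,
) -> list[SuperIndividual]:
    """Forced recruits entering at the end of a spin-up year.

    ``n_cohort`` juveniles enter the nursery area with body length
    ``L_1 - 3 * eps``, eps ~ U(0, 1), i.e. lengths in (17, 20] cm.
    """
    if not in_spinup:
        raise PopulationError(
            "forced recruitment is only valid during the spin-up decade"
        )
    if year_abundance <= 0:
        raise PopulationError("year abundance must be positive")
    pop: list[SuperIndividual] = []
    for i in range(params.n_cohort):
        sid = id_start + i
        rng = make_si_rng(master_seed, sid)
        L = params.L_1 - 3.0 * rng.random()
        m_struct = structural_mass(L, params)
        y, x = _place_random(sea.narea, rng)
        si = SuperIndividual(
            id=sid,
            abundance=year_abundance / params.n_cohort,
            age_days=365.0 - HATCH_DOY + 1.0,
            gender="f" if i % 2 == 0 else "m",
            stage=Stage.JUVENILE,
            L=L,
            M_struct=m_struct,
            energy_reserve=0.5 * params.E_max * m_struct * params.E_lipid,
            x=x,
            y=y,
            rng=rng,
        )
        si.fed_once = True
        pop.append(si)
    return pop


def transform_stage(
    si: SuperIndividual,
    doy: int,
    params: ParameterSet,
    sea: Seascape | None = None,
) -> SuperIndividual:
    """Advance the ontogenetic stage where thresholds are met.

    Eggs hatch into yolk-sac larvae at ``L_hatch`` after the 5-day
    development period; yolk-sac larvae become feeding larvae at 0.61 cm;
    larvae become juveniles at 3 cm (and settle into the nursery area);
    juveniles of length >= L_mat all mature together on February 1st.
    """
    if not si.alive:
        return si
    if si.stage == Stage.EGG and si.development >= params.egg_dev_days:
        si.stage = Stage.YOLK_SAC
        si.L = params.L_hatch
        si.M_struct = structural_mass(si.L, params)
    if si.stage == Stage.YOLK_SAC and si.L >= params.L_larva:
        si.stage = Stage.LARVA
        si.feeding = True  # first exogenous feeding stage
    if si.stage == Stage.LARVA and si.L >= params.L_juvenile:
        si.stage = Stage.JUVENILE
        if sea is not None and not sea.narea[si.patch]:
            ys, xs = np.nonzero(sea.narea)
            if ys.size:
                i = int(np.argmin((ys - si.y) ** 2 + (xs - si.x) ** 2))
                si.y, si.x = float(ys[i]), float(xs[i])
    if (
        si.stage == Stage.JUVENILE
        and si.L >= params.L_mat
        and doy == DOY_MATURATION
    ):
        si.stage = Stage.ADULT
        si.A_mat = si.age_years
        si.L_mat_attained = si.L
        # the new adult joins the spawning migration
        si.migrating = True
        si.migration_mode = "spawning"
    return si


def population_to_frame(pop: Iterable[SuperIndividual], p: ParameterSet) -> pd.DataFrame:
    """One row per SI, for checkpointing and diagnostics."""
    rows = []
    for si in pop:
        rows.append(
            {
                "id": si.id,
                "abundance": si.abundance,
                "age_days": si.age_days,
                "gender": si.gender,
                "stage": si.stage.name,
                "L": si.L,
                "M": si.total_mass(p),
                "M_struct": si.M_struct,
                "M_gon": si.M_gon,
                "energy_reserve": si.energy_reserve,
                "x": si.x,
                "y": si.y,
                "feeding": si.feeding,
                "migrating": si.migrating,
                "spawning": si.spawning,
            }
        )
    return pd.DataFrame(rows)
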