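"""Mortality channels, fishing-rate scheduling, and recruitment.

Mortality acts on a super-individual's abundance: the fraction dying over a
step of length t days is 1 - exp(-(M_back + F) t) with both rates per day.
SIs whose abundance falls below one are removed, as are SIs that starve
(total mass run down to structural mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dates import STEPS_PER_YEAR, month_of_doy, step_days_covered
from .parameters import ParameterSet
from .population import SuperIndividual, Stage, make_si_rng

__all__ = [
    "FishingSchedule",
    "background_mortality",
    "apply_mortality",
    "predation_mortality",
    "starvation_check",
    "recruit_emergent",
    "recruit_ricker",
    "DemographyError",
]

_EPS = 1e-12


class DemographyError(ValueError):
    pass


# number of 5-day steps whose start day falls in each month (365-day year)
_STEPS_IN_MONTH = tuple(
    sum(
        1
        for s in range(STEPS_PER_YEAR)
        if month_of_doy(s * 5 + 1) == m
    )
    for m in range(1, 13)
)


@dataclass
class FishingSchedule:
    """Annual F-at-age plus monthly catch fractions.

    ``annual_F``: mapping year -> mapping age -> F (year-1); a single
    mapping age -> F is treated as constant across years.  ``month_fractions``
    has 12 non-negative entries summing to one; the fraction of the annual F
    applied in a month is spread evenly over that month's steps.
    """

    annual_F: Mapping
    month_fractions: Sequence[float]

    def __post_init__(self) -> None:
        mf = np.asarray(self.month_fractions, dtype=float)
        if mf.shape != (12,):
            raise DemographyError("month_fractions must have 12 entries")
        if (mf < 0).any():
            raise DemographyError("month_fractions must be non-negative")
        if abs(mf.sum() - 1.0) > 1e-6:
            raise DemographyError(
                f"month_fractions sum to {mf.sum():.6f}, expected 1"
            )
        self.month_fractions = mf

    def F_at_age(self, year: int) -> Mapping[int, float]:
        sample = next(iter(self.annual_F.values()))
        if isinstance(sample, (int, float)):
            return self.annual_F  # constant across years
        if year in self.annual_F:
            return self.annual_F[year]
        years = sorted(self.annual_F)
        clamped = min(max(year, years[0]), years[-1])
        return self.annual_F[clamped]

    def step_F(self, year: int, doy: int, age_years: float) -> float:
        """Per-step instantaneous F for an SI of the given age (already
        integrated over the step: multiply abundance by exp(-step_F))."""
        Fa = self.F_at_age(year)
        age = min(int(age_years), max(int(a) for a in Fa))
        annual = float(Fa.get(age, 0.0))
        month = month_of_doy(doy)
        return annual * self.month_fractions[month - 1] / _STEPS_IN_MONTH[month - 1]

    @classmethod
    def from_csv(cls, f_at_age_path, month_fraction_path) -> "FishingSchedule":
        fa = pd.read_csv(f_at_age_path, index_col=0)
        fa.columns = [int(c) for c in fa.columns]
        annual = {int(y): {int(a): float(v) for a, v in row.items()}
                  for y, row in fa.iterrows()}
        mf = pd.read_csv(month_fraction_path)["fraction"].to_numpy(dtype=float)
        return cls(annual_F=annual, month_fractions=mf)


def background_mortality(si: SuperIndividual, p: ParameterSet) -> float:
    """Background mortality rate, day-1: M_e for eggs and larvae, the
    length-scaled M_a (L_mat / L) for juveniles, and M_a for adults."""
    if si.stage in (Stage.EGG, Stage.YOLK_SAC, Stage.LARVA):
        return p.M_e
    if si.stage == Stage.JUVENILE:
        return p.M_a * (p.L_mat / si.L)
    return p.M_a


def apply_mortality(
    si: SuperIndividual, M_back: float, F: float, step_days: float
) -> SuperIndividual:
    """Scale abundance by exp(-(M_back + F) * step_days); remove the SI if
    fewer than one individual remains.  ``F`` may already be integrated
    over the step (pass step_days consistent with the rates given)."""
    si.abundance *= math.exp(-(M_back + F) * step_days)
    si.F_applied = F
    if si.abundance < 1.0:
        si.alive = False
    return si


def predation_mortality(
    prey: SuperIndividual,
    predator: SuperIndividual,
    predator_IR_step: float,
    p: ParameterSet,
) -> SuperIndividual:
    """Cannibalism losses: the predator SI's individuals jointly remove
    ``abundance * IR * IR_cannibalism / prey mass`` prey individuals,
    floored at zero prey abundance."""
    prey_mass = prey.total_mass(p)
    if prey_mass <= 0:
        return prey
    eaten = predator.abundance * predator_IR_step * p.IR_cannibalism / prey_mass
    prey.abundance = max(prey.abundance - eaten, 0.0)
    if prey.abundance < 1.0:
        prey.alive = False
    return prey


def starvation_check(si: SuperIndividual) -> SuperIndividual:
    """Remove an SI whose total mass has been run down to its structural
    mass (reserves and gonads exhausted by a deficit).  Larvae are exempt
    until they have fed successfully once."""
    if si.stage == Stage.LARVA and not si.fed_once:
        return si
    if si.starving and si.energy_reserve <= _EPS and si.M_gon <= _EPS:
        si.alive = False
    return si


def recruit_emergent(
    total_egg_production: float,
    spawn_locations: Sequence[tuple[float, float]],
    n_new: int,
    params: ParameterSet,
    master_seed: int,
    id_start: int,
) -> list[SuperIndividual]:
    """Create ``n_new`` egg SIs sharing a batch's egg production equally,
    placed at (randomly chosen) spawners' batch locations."""
    if n_new <= 0:
        raise DemographyError("n_new must be positive")
    if total_egg_production <= 0 or not spawn_locations:
        return []
    out = []
    for i in range(n_new):
        sid = id_start + i
        rng = make_si_rng(master_seed, sid)
        y, x = spawn_locations[rng.randrange(len(spawn_locations))]
        si = SuperIndividual(
            id=sid,
            abundance=total_egg_production / n_new,
            age_days=0.0,
            gender="f" if i % 2 == 0 else "m",
            stage=Stage.EGG,
            L=0.0,
            M_struct=params.M_0,
            energy_reserve=0.0,
            x=float(x),
            y=float(y),
            rng=rng,
        )
        si.feeding = False
        out.append(si)
    return out


def recruit_ricker(
    SSB: float,
    mean_SST: float,
    coefficients: Mapping[str, float] | None,
) -> float:
    """SST-covariate Ricker recruitment R = a SSB exp(-b SSB + g SST).

    The coefficients are user-supplied configuration (keys ``alpha``,
    ``beta``, ``gamma``); there are no defaults.
    """
    if not coefficients:
        raise DemographyError(
            "Ricker recruitment requires user-supplied coefficients "
            "(alpha, beta, gamma)"
        )
    try:
        a = float(coefficients["alpha"])
        b = float(coefficients["beta"])
        g = float(coefficients["gamma"])
    except KeyError as e:
        raise DemographyError(f"missing Ricker coefficient {e.args[0]!r}") from None
    return a * SSB * math.exp(-b * SSB + g * mean_SST)
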