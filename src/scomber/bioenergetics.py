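"""Ingestion, maintenance, growth, reserves, fecundity and egg development:
the per-super-individual energy budget.

All physiological rates are stored per day and integrated over the number
of days a budget call covers.  Temperatures enter the metabolic equations
in kelvin.  Two Arrhenius forms appear, exactly as the model defines them:
the relative form exp(-(E_a/K)(1/T - 1/T_ref)) scales ingestion and growth,
while metabolic rates use the absolute form exp(-E_a/(K T)) with their own
normalizing constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .parameters import ParameterSet
from .population import (
    Stage,
    SuperIndividual,
    length_from_structural_mass,
    structural_mass,
)

__all__ = [
    "EnergyLedger",
    "arrhenius",
    "ingestion",
    "select_prey",
    "smr",
    "amr",
    "max_growth",
    "growth_increment",
    "grow",
    "reserves_update",
    "potential_fecundity",
    "batch_energy",
    "allocate_reproduction",
    "spawn_batch",
    "develop_egg",
    "step_energy_budget",
]

_EPS = 1e-12


@dataclass
class EnergyLedger:
    """Per-step energy audit for one SI (all energies in kJ).

    The ledger closes exactly:
    ``assimilated - maintenance - growth_cost - reproduction_cost
    - storage_cost - discarded - reserve_delta = 0``
    where ``reserve_delta`` is the net change of the lipid store (negative
    when reserves are drawn), ``storage_cost`` is the lipid-synthesis levy,
    ``discarded`` is surplus rejected at the reserve cap, and unmet
    maintenance (starvation pending) is tracked separately.
    """

    intake_g: float = 0.0        # ingested prey mass, g
    intake: float = 0.0          # ingested energy, kJ
    assimilated: float = 0.0
    maintenance: float = 0.0     # maintenance actually paid
    growth_cost: float = 0.0
    reproduction_cost: float = 0.0
    storage_cost: float = 0.0    # E_sl levy on energy routed to reserves
    discarded: float = 0.0       # surplus beyond the reserve cap
    unmet: float = 0.0           # maintenance the SI could not pay
    reserve_delta: float = 0.0   # net change of the lipid store

    def residual(self) -> float:
        return (
            self.assimilated
            - self.maintenance
            - self.growth_cost
            - self.reproduction_cost
            - self.storage_cost
            - self.discarded
            - self.reserve_delta
        )


# ---------------------------------------------------------------------------
# temperature scaling and rates
# ---------------------------------------------------------------------------

def arrhenius(sst_K: float, p: ParameterSet) -> float:
    """Relative Arrhenius factor; equals 1 at the reference temperature."""
    if sst_K <= 0:
        raise ValueError("absolute temperature must be positive")
    return math.exp(-(p.E_a / p.K) * (1.0 / sst_K - 1.0 / p.T_ref))


def ingestion(M: float, X: float, D: float, sst_K: float, p: ParameterSet) -> float:
    """Ingestion rate in g day-1 from a Beddington-DeAngelis response:

    IR = A(SST) * C_max * X / (X + h + c D) * M^(2/3)

    ``D`` is local mackerel density (g per patch) including the focal SI.
    Saturating in food, declining in consumer density.
    """
    denom = X + p.h + p.c * D
    if denom <= 0:
        return 0.0
    return arrhenius(sst_K, p) * p.C_max * X / denom * M ** (2.0 / 3.0)


def select_prey(
    si: SuperIndividual,
    cohabitants: Sequence[SuperIndividual],
    p: ParameterSet,
) -> SuperIndividual | None:
    """Pick a cannibalism victim: same patch, at least ``prey_size_ratio``
    times smaller, and below the absolute prey-length cutoff.  One eligible
    candidate is chosen uniformly at random."""
    patch = si.patch
    cands = [
        o
        for o in cohabitants
        if o.alive
        and o.id != si.id
        and o.patch == patch
        and o.L > 0
        and si.L >= p.prey_size_ratio * o.L
        and o.L < p.prey_max_length
    ]
    if not cands:
        return None
    return cands[si.rng.randrange(len(cands))]


def smr(M: float, sst_K: float, p: ParameterSet) -> float:
    """Standard metabolic rate, kJ day-1 (absolute-form Arrhenius)."""
    if M <= 0:
        raise ValueError("body mass must be positive")
    return p.a_SMR * M ** p.b_SMR * math.exp(-p.E_a / (p.K * sst_K))


def amr(M: float, V: float, sst_K: float, p: ParameterSet) -> float:
    """Active metabolic rate, kJ day-1; linear in swimming speed V."""
    if V < 0:
        raise ValueError("swimming speed must be non-negative")
    return p.a_AMR * M ** p.b_AMR * V ** p.c_AMR * math.exp(-p.E_a / (p.K * sst_K))


def max_growth(
    L: float,
    age_days: float,
    sst_K: float,
    p: ParameterSet,
    adult: bool = False,
    feeding: bool = True,
) -> float:
    """Maximum length increment, cm day-1.

    First growing season (< 240 days): Gompertz, dL = k_1 A L ln(L_1/L).
    Afterwards: von Bertalanffy, dL = k A (L_inf - L), with k doubled for
    adults since they grow only while feeding (half the year).
    """
    A = arrhenius(sst_K, p)
    if age_days < p.growth_switch_age:
        if L >= p.L_1 or L <= 0:
            return 0.0
        return p.k_1 * A * L * math.log(p.L_1 / L)
    if adult and not feeding:
        return 0.0
    k = 2.0 * p.k if adult else p.k
    return max(k * A * (p.L_inf - L), 0.0)


def growth_increment(
    L: float,
    age_days: float,
    sst_K: float,
    days: float,
    p: ParameterSet,
    adult: bool = False,
    feeding: bool = True,
) -> float:
    """Maximum length increment over ``days`` at constant SST.

    Integrates the growth laws exactly over the step (both have closed-form
    solutions), so a food-unlimited trajectory reproduces the analytic
    first-season Gompertz and later von Bertalanffy curves to numerical
    precision; the Euler rate would otherwise overshoot early growth.
    """
    A = arrhenius(sst_K, p)
    if age_days < p.growth_switch_age:
        if L >= p.L_1 or L <= 0:
            return 0.0
        # d(ln(L_1/L))/dt = -k_1 A ln(L_1/L)
        new_L = p.L_1 * math.exp(
            -math.log(p.L_1 / L) * math.exp(-p.k_1 * A * days)
        )
        return max(new_L - L, 0.0)
    if adult and not feeding:
        return 0.0
    k = 2.0 * p.k if adult else p.k
    if L >= p.L_inf:
        return 0.0
    new_L = p.L_inf - (p.L_inf - L) * math.exp(-k * A * days)
    return max(new_L - L, 0.0)


def grow(
    si: SuperIndividual, dL: float, available: float, p: ParameterSet
) -> float:
    """Convert a length increment into structural mass, paying
    ``dM (E_flesh + E_sf)``; when energy is short the realized growth is
    scaled down proportionally.  Returns the energy actually spent."""
    if dL < 0:
        raise ValueError("growth increment must be non-negative")
    if dL == 0.0 or available <= 0.0:
        return 0.0
    dM = structural_mass(si.L + dL, p) - si.M_struct
    if dM <= 0.0:
        return 0.0
    cost = dM * (p.E_flesh + p.E_sf)
    if cost > available:
        dM = available / (p.E_flesh + p.E_sf)
        cost = available
    si.M_struct += dM
    si.L = length_from_structural_mass(si.M_struct, p)
    return cost


def reserves_update(
    si: SuperIndividual, surplus: float, p: ParameterSet
) -> tuple[float, float, float, float]:
    """Route an energy surplus into, or a deficit out of, the lipid store.

    A surplus pays the lipid-synthesis cost E_sl per gram before storage
    and is capped at the maximum reserve (E_max of structural mass, in
    lipid-mass terms).  A deficit is drawn at E_lipid per gram; an empty
    store leaves the deficit unmet (starvation pending).

    Returns ``(reserve_delta, storage_cost, discarded, unmet)``.
    """
    if surplus >= 0.0:
        grams = surplus / (p.E_lipid + p.E_sl)
        cap_grams = max(p.E_max * si.M_struct - si.lipid_mass(p), 0.0)
        store_grams = min(grams, cap_grams)
        stored = store_grams * p.E_lipid
        cost = store_grams * p.E_sl
        discarded = surplus - stored - cost
        si.energy_reserve += stored
        return stored, cost, discarded, 0.0
    deficit = -surplus
    draw = min(deficit, si.energy_reserve)
    si.energy_reserve -= draw
    unmet = deficit - draw
    if unmet > _EPS:
        si.energy_reserve = 0.0
    return -draw, 0.0, 0.0, unmet


def potential_fecundity(L: float, p: ParameterSet) -> float:
    """Potential fecundity f_p = a_f L^b_f (eggs per female per season)."""
    return p.a_f * L ** p.b_f


def batch_energy(f_p: float, p: ParameterSet) -> float:
    """Energy cost of a maximum-sized egg batch, kJ:
    b_max = f_p M_0 (E_flesh + E_sf) / n_b."""
    return f_p * p.M_0 * (p.E_flesh + p.E_sf) / p.n_b


def allocate_reproduction(
    si: SuperIndividual, available: float, days: float, p: ParameterSet
) -> float:
    """Move energy into the current egg batch (gonads) at the inter-batch
    provisioning rate b_max / b_int.  Returns the energy allocated."""
    if not si.spawning or si.batches >= p.n_b or si.f_p <= 0:
        return 0.0
    b_max = batch_energy(si.f_p, p)
    gonad_energy = si.M_gon * (p.E_flesh + p.E_sf)
    want = min(b_max / p.b_int * days, b_max - gonad_energy)
    alloc = max(min(want, available), 0.0)
    si.M_gon += alloc / (p.E_flesh + p.E_sf)
    return alloc


def spawn_batch(si: SuperIndividual, p: ParameterSet) -> float:
    """Release the current batch.  Returns eggs per represented female
    (zero for males, whose equal investment is shed as spent gonad mass).
    Gonad mass resets; spawning ceases after n_b batches."""
    eggs = si.M_gon / p.M_0 if si.gender == "f" else 0.0
    si.eggs_spawned += eggs
    si.M_gon = 0.0
    si.batches += 1
    if si.f_p > 0:
        si.f_r = si.eggs_spawned / si.f_p
    if si.batches >= p.n_b:
        si.spawning = False
    return eggs


def realized_fecundity(si: SuperIndividual) -> float:
    return si.eggs_spawned / si.f_p if si.f_p > 0 else 0.0


def develop_egg(si: SuperIndividual, days: float) -> SuperIndividual:
    """Advance egg development; hatching itself is a stage transition."""
    if si.stage == Stage.EGG:
        si.development += days
    return si


# ---------------------------------------------------------------------------
# the per-step budget
# ---------------------------------------------------------------------------

def step_energy_budget(
    si: SuperIndividual,
    X: float,
    sst_C: float,
    density: float,
    p: ParameterSet,
    days: float | None = None,
    active: bool = False,
    active_speed: float = 0.0,
    prey: SuperIndividual | None = None,
    feeding_enabled: bool = True,
    reserve_floor: float = 0.0,
) -> EnergyLedger:
    """One time-step of the energy budget (excluding batch spawning, which
    the scheduler triggers on batch dates).

    Order of allocation: maintenance (from assimilate, then reserves),
    then reproduction provisioning for spawning adults (assimilate, then
    reserves), then growth (post-maintenance surplus only), then storage.
    Eggs and yolk-sac larvae are assumed energy-sufficient and are handled
    by the caller; larvae prioritise growth and do not store lipid.
    """
    led = EnergyLedger()
    if days is None:
        days = p.step_days
    sst_K = sst_C + 273.15
    stage = si.stage
    if stage in (Stage.EGG, Stage.YOLK_SAC):
        return led

    M = si.total_mass(p)

    # --- ingestion ------------------------------------------------------
    if si.feeding and feeding_enabled:
        ir = ingestion(M, X, density, sst_K, p)  # g day-1
        led.intake_g = ir * days
        if led.intake_g > 0:
            if prey is not None:
                prey_M = prey.total_mass(p)
                lipid_frac = prey.lipid_mass(p) / prey_M if prey_M > 0 else 0.0
                e_fish = lipid_frac * p.E_lipid + (1.0 - lipid_frac) * p.E_flesh
                e_per_g = (
                    p.IR_cannibalism * e_fish
                    + (1.0 - p.IR_cannibalism) * p.E_phyto
                )
            else:
                e_per_g = p.E_phyto
            led.intake = led.intake_g * e_per_g
            si.fed_once = True
    led.assimilated = p.A_e * led.intake
    available = led.assimilated

    # --- maintenance ----------------------------------------------------
    if active:
        maint_due = amr(M, active_speed, sst_K, p) * days
    else:
        maint_due = smr(M, sst_K, p) * days
    pay = min(available, maint_due)
    available -= pay
    shortfall = maint_due - pay
    deficit_drawn = 0.0
    maint_drawn = 0.0
    if shortfall > 0.0 and stage >= Stage.JUVENILE:
        delta, _, _, unmet = reserves_update(si, -shortfall, p)
        deficit_drawn = maint_drawn = -delta
        led.unmet = unmet
        led.maintenance = pay + deficit_drawn
    elif shortfall > 0.0:
        # larvae carry no reserves; unmet maintenance is recorded but only
        # starves them once they have fed (growth-priority rule)
        led.unmet = shortfall
        led.maintenance = pay
    else:
        led.maintenance = maint_due

    # --- reproduction (spawning adults; outranks growth) ----------------
    if stage == Stage.ADULT and si.spawning:
        # batch provisioning may draw on the lipid store (it exists to fund
        # spawning through the fast) but not below the projected
        # maintenance requirement until feeding resumes (``reserve_floor``):
        # short reserves reduce batch size rather than kill the spawner
        spendable = available + max(si.energy_reserve - reserve_floor, 0.0)
        alloc = allocate_reproduction(si, spendable, days, p)
        from_assim = min(alloc, available)
        available -= from_assim
        from_reserve = alloc - from_assim
        if from_reserve > 0.0:
            delta, _, _, _ = reserves_update(si, -from_reserve, p)
            deficit_drawn += -delta
        led.reproduction_cost = alloc

    # --- growth ---------------------------------------------------------
    if stage >= Stage.LARVA:
        dL = growth_increment(
            si.L,
            si.age_days,
            sst_K,
            days,
            p,
            adult=stage == Stage.ADULT,
            feeding=si.feeding,
        )
        led.growth_cost = grow(si, dL, available, p)
        available -= led.growth_cost

    # --- storage --------------------------------------------------------
    if stage >= Stage.JUVENILE and available > 0.0:
        stored, cost, discarded, _ = reserves_update(si, available, p)
        led.storage_cost = cost
        led.discarded = discarded
        led.reserve_delta = stored - deficit_drawn
    else:
        # larvae do not store: any surplus is shed
        led.discarded = max(available, 0.0)
        led.reserve_delta = -deficit_drawn

    # starvation flag (removal decision belongs to demography): total mass
    # ran down to structural mass because maintenance could not be met.
    # Spending the store on reproduction alone is not lethal by itself;
    # a spent fish dies only once it fails to cover maintenance.
    if (
        si.energy_reserve <= _EPS
        and si.M_gon <= _EPS
        and (maint_drawn > 0.0 or led.unmet > _EPS)
    ):
        si.starving = True
    return led
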