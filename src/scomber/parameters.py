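"""Model constants, unit conventions, and fishing scenarios.

All rate and normalizing constants are stored in units of 1/day and converted
to the 5-day time-step where they are integrated.  Internal unit convention:
energies in kJ, masses in g wet weight, lengths in cm, velocities in km h-1,
temperatures in kelvin for metabolic equations and degrees C for behavioural
thresholds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "load_parameters",
    "scenario_F",
    "ParameterError",
    "F_SCENARIOS",
]


class ParameterError(ValueError):
    """Raised for unknown parameter names or out-of-range values."""


# unit tag per field (documentation + serialization metadata)
UNITS: dict[str, str] = {
    "a_AMR": "kJ day-1 g^-b_AMR (km h-1)^-c_AMR",
    "A_e": "proportion of ingested energy",
    "a_f": "eggs cm^-b_f",
    "A_r": "dimensionless (caudal fin aspect ratio)",
    "a_SMR": "kJ day-1 g^-b_SMR",
    "a_v": "km h-1 cm^-b_v",
    "b_AMR": "dimensionless",
    "b_f": "dimensionless",
    "b_SMR": "dimensionless",
    "b_v": "dimensionless",
    "c": "g patch-1 weighting (predator density dependence)",
    "c_AMR": "dimensionless",
    "C_max": "g g-1 day-1",
    "c_v": "dimensionless",
    "E_a": "eV",
    "E_flesh": "kJ g-1",
    "E_lipid": "kJ g-1",
    "E_max": "proportion of structural mass",
    "E_phyto": "kJ g-1",
    "E_sf": "kJ g-1",
    "E_sl": "kJ g-1",
    "h": "g m-2",
    "IR_cannibalism": "proportion of ingestion rate",
    "k": "day-1",
    "K": "eV K-1",
    "k_1": "day-1",
    "L_1": "cm",
    "L_inf": "cm",
    "L_hatch": "cm",
    "L_mat": "cm",
    "M_a": "day-1",
    "M_e": "day-1",
    "n_b": "batches season-1",
    "SST_lim": "degC",
    "t_max": "days",
    # constants not printed in the source table; configurable defaults
    "T_ref": "K",
    "a_w": "g cm^-b_w",
    "b_w": "dimensionless",
    "M_0": "g (egg wet mass)",
    "b_int": "days (inter-batch interval)",
    "t_0": "days (von Bertalanffy adjustment)",
    "growth_switch_age": "days (first-season -> von Bertalanffy switch)",
    "step_days": "days per time-step",
    "n_cohort": "new super-individuals year-1",
    "max_age_years": "years",
    "season_length": "days (spawning season)",
    "L_larva": "cm (yolk-sac -> feeding larva)",
    "L_juvenile": "cm (larva -> juvenile)",
    "prey_size_ratio": "dimensionless (predator/prey length ratio)",
    "prey_max_length": "cm (absolute cannibalism prey-length cutoff)",
    "egg_dev_days": "days",
    "stop_distance_max": "patches (feeding-migration stop distance)",
}

# rates expressed per day that scale linearly with the step length
RATE_PARAMS = ("C_max", "k", "k_1", "M_a", "M_e")

# efficiencies/proportions constrained to (0, 1]
_EFFICIENCIES = ("A_e",)
# proportions constrained to [0, 1)
_PROPORTIONS = ("IR_cannibalism",)
# strictly non-negative quantities
_NONNEGATIVE = (
    "a_AMR", "a_f", "A_r", "a_SMR", "a_v", "b_AMR", "b_f", "b_SMR", "b_v",
    "c", "c_AMR", "C_max", "c_v", "E_a", "E_flesh", "E_lipid", "E_max",
    "E_phyto", "E_sf", "E_sl", "h", "k", "K", "k_1", "L_1", "L_inf",
    "L_hatch", "L_mat", "M_a", "M_e", "n_b", "t_max", "T_ref", "a_w", "b_w",
    "M_0", "b_int", "step_days", "n_cohort", "max_age_years",
    "season_length", "L_larva", "L_juvenile", "prey_size_ratio",
    "prey_max_length", "egg_dev_days", "stop_distance_max",
)


@dataclass(frozen=True)
class ParameterSet:
    """Every model constant, stored per day, with unit tags in ``UNITS``."""

    # --- metabolic / movement normalizers -------------------------------
    a_AMR: float = 8.86e7           # active metabolic rate normalizer
    A_e: float = 0.95               # assimilation efficiency
    a_f: float = 8.80               # fecundity normalizer
    A_r: float = 4.01               # caudal fin aspect ratio
    a_SMR: float = 0.45e8           # standard metabolic rate normalizer
    a_v: float = 0.15               # swimming speed normalizer
    b_AMR: float = 0.75
    b_f: float = 3.02
    b_SMR: float = 0.75
    b_v: float = 0.62
    c: float = 9.71e-11             # predator density dependence strength
    c_AMR: float = 1.0
    C_max: float = 0.69             # maximum consumption, g g-1 day-1
    c_v: float = 0.35
    E_a: float = 0.5                # activation energy, eV
    E_flesh: float = 7.00
    E_lipid: float = 39.3
    E_max: float = 0.78             # max lipid store, proportion of M_struct
    E_phyto: float = 6.02
    E_sf: float = 3.60              # cost of synthesizing flesh
    E_sl: float = 14.7              # cost of synthesizing lipid
    h: float = 1.26                 # half-saturation, g m-2
    IR_cannibalism: float = 0.064
    k: float = 8.6e-4               # von Bertalanffy growth constant, day-1
    K: float = 8.62e-5              # Boltzmann constant, eV K-1
    k_1: float = 0.025              # first-season max growth rate, day-1
    L_1: float = 20.0               # max length after first growing season
    L_inf: float = 42.4
    L_hatch: float = 0.3
    L_mat: float = 26.2
    M_a: float = 0.00041            # background adult mortality, day-1
    M_e: float = 0.287              # background early mortality, day-1
    n_b: int = 5                    # egg batches per season
    SST_lim: float = 7.0            # lower temperature limit, degC
    t_max: float = 55.0             # age of maximum first-season growth

    # --- constants not printed in the source table (configurable) -------
    T_ref: float = 283.15           # reference temperature, K (10 degC)
    a_w: float = 0.0049             # length -> structural mass normalizer
    b_w: float = 3.17               # length -> structural mass exponent
    M_0: float = 0.001              # egg wet mass, g
    b_int: float = 12.0             # inter-batch interval, days
    t_0: float = 0.0                # von Bertalanffy age adjustment, days
    growth_switch_age: int = 240    # days; Gompertz -> von Bertalanffy
    step_days: int = 5
    n_cohort: int = 70
    max_age_years: int = 15
    season_length: float = 60.0     # spawning season, days
    L_larva: float = 0.61           # yolk-sac larva -> feeding larva
    L_juvenile: float = 3.0         # larva -> juvenile
    prey_size_ratio: float = 3.5
    prey_max_length: float = 0.33   # absolute prey-length cutoff, as printed
    egg_dev_days: int = 5
    stop_distance_max: int = 10

    def __post_init__(self) -> None:
        for name in _EFFICIENCIES:
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(
                    f"{name} = {v!r} outside (0, 1]; efficiencies must be "
                    "proportions"
                )
        for name in _PROPORTIONS:
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} = {v!r} outside [0, 1)")
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} = {v!r} must be non-negative")
        if not (0.0 < self.E_max <= 1.0):
            raise ParameterError(
                f"E_max = {self.E_max!r} outside (0, 1]"
            )
        if abs(self.n_b * self.b_int - self.season_length) > 1e-9:
            raise ParameterError(
                f"n_b * b_int = {self.n_b * self.b_int} does not equal the "
                f"spawning-season length {self.season_length} days"
            )

    # -- unit/time-step helpers ------------------------------------------
    def per_step(self, name: str) -> float:
        """A per-day rate converted to the configured time-step."""
        if name not in RATE_PARAMS:
            raise ParameterError(f"{name!r} is not a per-day rate parameter")
        return getattr(self, name) * self.step_days

    def unit(self, name: str) -> str:
        try:
            return UNITS[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    @property
    def reserve_cap_per_gram(self) -> float:
        """Maximum lipid energy per gram of structural mass (kJ g-1)."""
        return self.E_max * self.E_lipid

    # -- (de)serialization -----------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def replace(self, **overrides: float) -> "ParameterSet":
        return load_parameters({"parameters": {**self.to_dict(), **overrides}})


_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}
_INT_FIELDS = {
    f.name for f in dataclasses.fields(ParameterSet) if f.type == "int"
}


def load_parameters(config: Mapping | str | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a configuration document.

    ``config`` may be ``None`` (all defaults), a mapping with an optional
    ``parameters`` section, or a YAML string of the same shape.  Unknown
    names and out-of-range values are rejected.
    """
    if config is None:
        return ParameterSet()
    if isinstance(config, str):
        config = yaml.safe_load(config) or {}
    if not isinstance(config, Mapping):
        raise ParameterError("configuration must be a mapping or YAML text")
    overrides = config.get("parameters", config)
    if overrides is None:
        overrides = {}
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise ParameterError(
            "unknown parameter name(s): " + ", ".join(sorted(unknown))
        )
    coerced = {}
    for name, value in overrides.items():
        if not isinstance(value, (int, float)):
            raise ParameterError(f"{name} = {value!r} is not numeric")
        coerced[name] = int(value) if name in _INT_FIELDS else float(value)
    return ParameterSet(**coerced)


# multipliers applied to the mean historical F-at-age; the F_MSY multiplier
# 0.83 maps the historical mean over ages 4-8 (0.277 yr-1) onto 0.23 yr-1,
# and the F_lim multiplier 1.66 onto 0.46 yr-1
F_SCENARIOS: dict[str, float] = {
    "historical-mean": 1.0,
    "zero": 0.0,
    "fmsy": 0.83,
    "flim": 1.66,
}


def scenario_F(
    mean_F_at_age: Mapping[int, float], scenario: str
) -> dict[int, float]:
    """Scale a mean-historical F-at-age vector for a management scenario.

    ``mean_F_at_age`` maps age (years) to annual instantaneous fishing
    mortality; ages 0..15 must all be present.
    """
    key = scenario.lower().replace("_", "-")
    if key not in F_SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; expected one of "
            + ", ".join(sorted(F_SCENARIOS))
        )
    required = set(range(16))
    missing = sorted(required - {int(a) for a in mean_F_at_age})
    if missing:
        raise ParameterError(
            "F-at-age vector is missing ages: "
            + ", ".join(str(a) for a in missing)
        )
    mult = F_SCENARIOS[key]
    return {int(a): float(f) * mult for a, f in mean_F_at_age.items()}
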