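"""Generators for every input the simulator and its tests need: a small
runnable world, forcing files, numbers-at-age and fishing tables, and
pseudo-observations with known ground truth.

Everything is deterministic under a master seed and writes the same CSV
dialects the production readers consume.  The small world relaxes the
1050-SI rule behind an explicit test-scale flag; production configurations
keep the strict validator.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .evaluation import targets_from_outputs
from .scheduler import RunOutputs, _default_mean_F, _default_numbers_at_age

__all__ = [
    "FixtureSpec",
    "make_world_small",
    "make_pseudo_observations",
    "make_simulator",
]


@dataclass
class FixtureSpec:
    ny: int = 40
    nx: int = 40
    n_si: int = 105                 # test scale: 7 SIs per age class
    years: int = 5                  # forcing horizon
    spinup_years: int = 2
    run_years: int = 3
    start_year: int = 2000
    true_h: float = 1.26            # ground truth for recovery experiments
    true_c: float = 9.71e-11
    true_M_e: float = 0.287
    presence_noise: float = 0.1     # observation label-flip rate
    seed: int = 0


def make_world_small(
    spec: FixtureSpec | None = None, outdir: str | pathlib.Path | None = None
) -> dict:
    """A complete runnable configuration: 40x40 synthetic grid, 105 SIs,
    multi-year synthetic forcing, fishing tables and numbers-at-age.

    Returns the configuration mapping; when ``outdir`` is given the
    numbers-at-age and fishing tables are also written as CSV and the
    configuration as YAML, byte-identical for identical seeds.
    """
    spec = spec or FixtureSpec()
    naa = _default_numbers_at_age()
    mean_F = _default_mean_F()
    month_fractions = [
        0.13, 0.11, 0.08, 0.03, 0.02, 0.02, 0.03, 0.05, 0.10, 0.15, 0.15, 0.13,
    ]
    config = {
        "parameters": {
            "h": spec.true_h,
            "c": spec.true_c,
            "M_e": spec.true_M_e,
        },
        "scenario": "historical-mean",
        "grid": {"ny": spec.ny, "nx": spec.nx, "bathymetry": "synthetic"},
        "forcing": {"year0": spec.start_year, "n_years": spec.years},
        "initial": {"numbers_at_age": naa},
        "fishing": {
            "mean_F_at_age": mean_F,
            "month_fractions": month_fractions,
        },
        "schedule": {
            "start_year": spec.start_year,
            "spinup_years": spec.spinup_years,
            "run_years": spec.run_years,
            "n_si": spec.n_si,
            "allow_test_scale": spec.n_si % 1050 != 0,
            "spinup_recruitment": naa[0],
            "recruitment": "emergent",
        },
        "outputs": {},
    }
    if outdir is not None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"age": list(naa), "abundance": list(naa.values())}
        ).to_csv(out / "numbers_at_age.csv", index=False)
        pd.DataFrame(
            {str(a): {spec.start_year: f} for a, f in mean_F.items()}
        ).rename_axis("year").to_csv(out / "f_at_age.csv")
        pd.DataFrame(
            {"month": range(1, 13), "fraction": month_fractions}
        ).to_csv(out / "month_fractions.csv", index=False)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config, sort_keys=True)
        )
    return config


def make_simulator(base_config: Mapping, years: list[int] | None = None):
    """A simulator callable for rejection-ABC calibration of (h, c, M_e):
    ``simulator(params, seed)`` runs the configured world with the three
    feeding/early-mortality parameters overridden and returns the fixed-grid
    calibration series."""
    from .scheduler import run as run_world

    def simulator(params: Mapping[str, float], seed: int) -> dict:
        cfg = {k: (dict(v) if isinstance(v, Mapping) else v)
               for k, v in base_config.items()}
        cfg["parameters"] = {**dict(cfg.get("parameters", {})), **dict(params)}
        out = run_world(cfg, seed=seed)
        return targets_from_outputs(out, years=years)

    return simulator


def make_pseudo_observations(
    outputs: RunOutputs,
    noise: float = 0.0,
    seed: int = 0,
) -> dict:
    """Perturbed targets for calibration-recovery and skill tests.

    Returns a mapping with ``targets`` (SSB and weight-at-age arrays with
    multiplicative Gaussian noise of the stated relative magnitude) and
    ``presence`` (July/August presence grids with labels flipped at the
    stated rate).
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)

    clean = targets_from_outputs(outputs)
    targets = {
        name: arr * (1.0 + noise * rng.standard_normal(arr.shape))
        for name, arr in clean.items()
    }

    presence = {}
    for year, pres in outputs.presence.items():
        labels = pres > 0
        flips = rng.random(labels.shape) < noise
        presence[year] = np.where(flips, ~labels, labels)
    return {"targets": targets, "presence": presence}
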