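"""Rejection-ABC calibration and presence/absence skill validation.

Calibration targets the three parameters that cannot be taken from the
literature — the half-saturation constant h, the competition strength c,
and the background early mortality M_e — by fitting the simulator to SSB
and weight-at-age series.  Validation scores predicted summer density maps
against presence/absence observations with a threshold optimised before
computing sensitivity and specificity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ABCResult",
    "SkillResult",
    "abc_calibrate",
    "optimise_threshold",
    "targets_from_outputs",
    "EvaluationError",
]


def targets_from_outputs(
    outputs,
    years: Sequence[int] | None = None,
    ages: Sequence[int] = tuple(range(3, 13)),
) -> dict[str, np.ndarray]:
    """Extract calibration series on a fixed year x age grid so simulated
    and observed arrays always align: spawning-time SSB per year and mean
    weight-at-age (ages three to twelve) per year, zero-filled where a
    class is empty."""
    if years is None:
        years = sorted(outputs.ssb_spawning)
    ssb = np.array([outputs.ssb_spawning.get(y, 0.0) for y in years])
    waa = np.array(
        [
            [outputs.weight_at_age_spawning.get(y, {}).get(a, 0.0) for a in ages]
            for y in years
        ]
    )
    return {"ssb": ssb, "weight_at_age": waa}


class EvaluationError(ValueError):
    pass


@dataclass
class ABCResult:
    priors: dict                    # name -> (lo, hi)
    draws: pd.DataFrame             # one row per simulation
    costs: np.ndarray
    acceptance_fraction: float
    accepted: pd.DataFrame          # the best draws (posterior sample)
    posterior_summary: pd.DataFrame  # mean / quantiles per parameter
    output_quantiles: dict = field(default_factory=dict)

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        q = (1.0 - level) / 2.0
        v = self.accepted[name].to_numpy()
        return float(np.quantile(v, q)), float(np.quantile(v, 1.0 - q))

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        d = self.draws.copy()
        d["cost"] = self.costs
        d.to_csv(out / "abc_draws.csv", index=False)
        self.accepted.to_csv(out / "abc_accepted.csv", index=False)
        summary = {
            "acceptance_fraction": self.acceptance_fraction,
            "posterior": {
                name: {
                    "mean": float(self.accepted[name].mean()),
                    "ci95": list(self.credible_interval(name)),
                }
                for name in self.priors
            },
        }
        (out / "abc_summary.json").write_text(json.dumps(summary, indent=2))


@dataclass
class SkillResult:
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def load_targets_csv(ssb_path, weight_at_age_path) -> dict[str, np.ndarray]:
    """Calibration targets from CSV: an SSB series with columns
    (year, ssb) and a weight-at-age table with columns (year, age, weight),
    pivoted onto a dense year x age grid."""
    ssb = pd.read_csv(ssb_path).sort_values("year")["ssb"].to_numpy(float)
    waa = (
        pd.read_csv(weight_at_age_path)
        .pivot(index="year", columns="age", values="weight")
        .sort_index()
        .fillna(0.0)
        .to_numpy(float)
    )
    return {"ssb": ssb, "weight_at_age": waa}


def load_presence_csv(path) -> pd.DataFrame:
    """Presence/absence observations with columns (cell, year, presence)."""
    df = pd.read_csv(path)
    missing = {"cell", "year", "presence"} - set(df.columns)
    if missing:
        raise EvaluationError(f"presence CSV missing columns: {sorted(missing)}")
    return df


def _normalized_cost(
    sim: Mapping[str, np.ndarray], targets: Mapping[str, np.ndarray]
) -> float:
    """Sum of squared deviations, each dataset normalized by its own
    variance so that units cancel across datasets."""
    total = 0.0
    for name, obs in targets.items():
        obs = np.asarray(obs, dtype=float).ravel()
        pred = np.asarray(sim[name], dtype=float).ravel()
        if pred.shape != obs.shape:
            raise EvaluationError(
                f"target {name!r}: simulated shape {pred.shape} != "
                f"observed shape {obs.shape}"
            )
        var = float(np.var(obs))
        if var <= 0:
            var = 1.0
        total += float(np.sum((pred - obs) ** 2)) / var
    return total


def abc_calibrate(
    simulator: Callable[[Mapping[str, float], int], Mapping[str, np.ndarray]],
    priors: Mapping[str, tuple[float, float]],
    targets: Mapping[str, np.ndarray],
    n_sims: int,
    accept_frac: float = 0.01,
    seed: int = 0,
    latin_hypercube: bool = False,
) -> ABCResult:
    """Rejection ABC: draw parameters from uniform priors, simulate, score
    each draw with the variance-normalized sum of squared deviations, and
    accept the best ``accept_frac`` of draws as the posterior sample.

    ``simulator(params, seed)`` must return a mapping with one array per
    target series.  A failing draw is recorded with infinite cost.  The
    same child seed is passed to every draw so that differences in cost
    reflect the parameters alone.
    """
    if not priors:
        raise EvaluationError("at least one prior is required")
    for name, (lo, hi) in priors.items():
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise EvaluationError(f"prior for {name!r} must be finite with lo < hi")
    if not 0.0 < accept_frac <= 1.0:
        raise EvaluationError("accept_frac must be in (0, 1]")
    if n_sims < math.ceil(1.0 / accept_frac):
        raise EvaluationError(
            f"n_sims = {n_sims} cannot resolve an acceptance fraction of "
            f"{accept_frac} (need at least {math.ceil(1.0 / accept_frac)})"
        )

    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    names = list(priors)
    lo = np.array([priors[n][0] for n in names])
    hi = np.array([priors[n][1] for n in names])
    if latin_hypercube:
        from scipy.stats import qmc

        u = qmc.LatinHypercube(d=len(names), seed=rng).random(n_sims)
    else:
        u = rng.random((n_sims, len(names)))
    samples = lo + u * (hi - lo)
    draws = pd.DataFrame(samples, columns=names)

    child_seed = int(rng.integers(0, 2**31 - 1))
    costs = np.empty(n_sims)
    for i in range(n_sims):
        params = {n: float(draws.iloc[i][n]) for n in names}
        try:
            sim = simulator(params, child_seed)
            costs[i] = _normalized_cost(sim, targets)
        except Exception:  # noqa: BLE001 - a failed draw scores infinity
            costs[i] = np.inf

    n_accept = max(int(math.ceil(accept_frac * n_sims)), 1)
    order = np.argsort(costs, kind="stable")
    accepted = draws.iloc[order[:n_accept]].reset_index(drop=True)

    summary = pd.DataFrame(
        {
            "mean": accepted.mean(),
            "q2.5": accepted.quantile(0.025),
            "median": accepted.quantile(0.5),
            "q97.5": accepted.quantile(0.975),
        }
    )
    return ABCResult(
        priors=dict(priors),
        draws=draws,
        costs=costs,
        acceptance_fraction=accept_frac,
        accepted=accepted,
        posterior_summary=summary,
    )


def optimise_threshold(
    predicted_density: np.ndarray,
    observed_presence: np.ndarray,
    objective: str = "youden",
) -> SkillResult:
    """Exhaustively scan candidate density thresholds and return the one
    maximizing the objective (Youden's J = sensitivity + specificity - 1,
    or classification accuracy).

    A cell is classed as a presence when its predicted density is >= the
    threshold.  Predictions and observations must already be pooled over
    the surveyed cells/years.
    """
    dens = np.asarray(predicted_density, dtype=float).ravel()
    obs = np.asarray(observed_presence).astype(bool).ravel()
    if dens.shape != obs.shape:
        raise EvaluationError("prediction and observation shapes differ")
    n_pos = int(obs.sum())
    n_neg = int(obs.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError(
            "observations contain a single class; sensitivity or "
            "specificity is undefined"
        )
    # candidate set: every observed density value plus one above the max,
    # so the scan is exhaustive over distinct confusion tables
    cands = np.unique(dens)
    cands = np.append(cands, cands[-1] + 1.0)
    best: SkillResult | None = None
    for t in cands:
        pred = dens >= t
        tp = int(np.sum(pred & obs))
        fp = int(np.sum(pred & ~obs))
        tn = n_neg - fp
        fn = n_pos - tp
        sens = tp / n_pos
        spec = tn / n_neg
        score = (
            sens + spec - 1.0
            if objective == "youden"
            else (tp + tn) / obs.size
        )
        if best is None or score > _score(best, objective):
            best = SkillResult(float(t), sens, spec, tp, fp, tn, fn)
    return best


def _score(r: SkillResult, objective: str) -> float:
    if objective == "youden":
        return r.youden
    return (r.tp + r.tn) / (r.tp + r.fp + r.tn + r.fn)
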