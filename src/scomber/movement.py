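"""Migrations, gradient-area-search foraging, constrained random walks,
and northward spawning movement.

Positions are continuous, in patch units (one unit = one cell edge).  North
is +y and east is +x.  Swimming velocities are in km h-1 and are converted
to patch units through the cell edge length.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet
from .population import SuperIndividual
from .seascape import Seascape, NEIGHBOURS_4
from .bioenergetics import arrhenius

__all__ = [
    "v_min",
    "search_radius_patches",
    "migration_step",
    "profitability",
    "gas_daily_step",
    "random_walk_in_area",
    "spawning_move",
]

HOURS_PER_DAY = 24.0


def v_min(L: float, p: ParameterSet) -> float:
    """Minimum swimming velocity (km h-1): a_v * L^b_v * A_r^c_v.

    Strictly increasing in body length, which lets larger individuals reach
    destination areas first.
    """
    if L <= 0:
        raise ValueError(f"body length must be positive, got {L}")
    return p.a_v * L ** p.b_v * p.A_r ** p.c_v


def search_radius_patches(si: SuperIndividual, sea: Seascape, p: ParameterSet) -> float:
    """Per-time-step search radius in patch units."""
    return v_min(si.L, p) * HOURS_PER_DAY * p.step_days / sea.cell_km


def migration_step(
    si: SuperIndividual,
    sea: Seascape,
    R: np.ndarray,
    p: ParameterSet,
    constrain_shelf: bool = False,
) -> SuperIndividual:
    """Move a migrating SI to the lowest-R patch within its search area.

    Ties are broken uniformly at random.  When the spawning/feeding shelf
    constraint is active only shelf-edge patches are candidates.  The
    migration ends once R at the new position is within ``stop_distance``
    (zero except for the feeding migration, which halts at a randomly drawn
    distance from the entrance to the feeding grounds).
    """
    if not si.migrating:
        return si
    y0, x0 = si.patch
    radius = search_radius_patches(si, sea, p)
    best_r = None
    best: list[tuple[int, int]] = []
    for yy, xx in sea.patches_within(y0, x0, radius):
        if constrain_shelf and not sea.shelf_edge[yy, xx]:
            continue
        r = R[yy, xx]
        if r < 0:  # land or unreachable
            continue
        if best_r is None or r < best_r:
            best_r, best = r, [(yy, xx)]
        elif r == best_r:
            best.append((yy, xx))
    if not best:
        return si  # no reachable candidate; stay put
    yy, xx = best[si.rng.randrange(len(best))] if len(best) > 1 else best[0]
    si.y, si.x = float(yy), float(xx)
    if R[yy, xx] <= si.stop_distance:
        si.migrating = False
        si.migration_mode = ""
    return si


def profitability(sea: Seascape, y: int, x: int, p: ParameterSet) -> float:
    """Dimensionless feeding-profitability cue of a patch.

    c_dd = A(SST) * p_photo * X / (X + h + c * D), forced to zero below the
    7 degC avoidance threshold and on land.
    """
    if not sea.is_ocean(y, x):
        return 0.0
    sst = sea.SST[y, x]
    if sst < p.SST_lim:
        return 0.0
    X = sea.X[y, x]
    A = arrhenius(sst + 273.15, p)
    return A * sea.p_photo[y, x] * X / (X + p.h + p.c * sea.D[y, x])


def _patch_ok(sea: Seascape, y: float, x: float, p: ParameterSet) -> bool:
    yy, xx = int(round(y)), int(round(x))
    return sea.is_ocean(yy, xx) and sea.SST[yy, xx] >= p.SST_lim


def gas_daily_step(
    si: SuperIndividual,
    sea: Seascape,
    p: ParameterSet,
    random_component: bool = True,
    speed_noise: bool = True,
) -> float:
    """One day of gradient area search.  Returns km swum under own power.

    The day splits into a directed half (heading persistence while the cue
    improves, otherwise a gradient step towards the most profitable
    neighbouring patch), a random half in a non-southward direction, and
    passive current displacement.  The cue is zero on cold (<7 degC)
    patches; a random heading towards cold water is reversed, and current
    displacement onto cold water or land is abandoned for the centroid of
    the nearest suitable patch.
    """
    cell = sea.cell_km
    y0, x0 = si.patch
    profit_now = profitability(sea, y0, x0, p)
    eps = si.rng.random() if speed_noise else 0.0
    vr = v_min(si.L, p) * (1.0 + eps)
    half_day_patches = vr * (HOURS_PER_DAY / 2.0) / cell
    swim_km = 0.0

    # --- directed half-day ---------------------------------------------
    if profit_now > si.prev_profit and si.prev_profit >= 0.0:
        dx, dy = si.heading
    else:
        gx = profitability(sea, y0, x0 + 1, p) - profitability(sea, y0, x0 - 1, p)
        gy = profitability(sea, y0 + 1, x0, p) - profitability(sea, y0 - 1, x0, p)
        norm = math.hypot(gx, gy)
        if norm > 0.0:
            dx, dy = gx / norm, gy / norm
        else:
            dx, dy = si.heading
    nx_, ny_ = si.x + dx * half_day_patches, si.y + dy * half_day_patches
    if _patch_ok(sea, ny_, nx_, p):
        si.x, si.y = nx_, ny_
        si.heading = (dx, dy)
        swim_km += vr * (HOURS_PER_DAY / 2.0)

    # --- random, non-southward half-day --------------------------------
    if random_component:
        theta = si.rng.random() * math.pi  # east through north to west
        rx, ry = math.cos(theta), math.sin(theta)  # ry >= 0: never southward
        nx_, ny_ = si.x + rx * half_day_patches, si.y + ry * half_day_patches
        if not _patch_ok(sea, ny_, nx_, p):
            # heading towards an intolerably cold patch (or land): reverse
            rx, ry = -rx, -ry
            nx_, ny_ = si.x + rx * half_day_patches, si.y + ry * half_day_patches
        if _patch_ok(sea, ny_, nx_, p):
            si.x, si.y = nx_, ny_
            swim_km += vr * (HOURS_PER_DAY / 2.0)

    # --- current displacement ------------------------------------------
    yy, xx = si.patch
    u = sea.U[yy, xx]
    v = sea.V[yy, xx]
    nx_, ny_ = si.x + u * HOURS_PER_DAY / cell, si.y + v * HOURS_PER_DAY / cell
    if _patch_ok(sea, ny_, nx_, p):
        si.x, si.y = nx_, ny_
    else:
        sy, sx = sea.nearest_suitable(si.y, si.x, p.SST_lim)
        si.y, si.x = float(sy), float(sx)

    si.prev_profit = profit_now
    return swim_km


def random_walk_in_area(
    si: SuperIndividual,
    sea: Seascape,
    area_mask: np.ndarray,
    p: ParameterSet,
) -> SuperIndividual:
    """True random walk: a uniform choice among same-area patches within
    the SI's per-step search radius; stays put when none is in reach."""
    y0, x0 = si.patch
    radius = search_radius_patches(si, sea, p)
    cands = [
        (yy, xx)
        for yy, xx in sea.patches_within(y0, x0, radius)
        if area_mask[yy, xx]
    ]
    if not cands:
        return si
    yy, xx = cands[si.rng.randrange(len(cands))]
    si.y, si.x = float(yy), float(xx)
    return si


def spawning_move(si: SuperIndividual, sea: Seascape, p: ParameterSet) -> SuperIndividual:
    """After spawning a batch, move to the nearest patch strictly north of
    the current position with 10 < SST < 14 degC; failing that, a random
    neighbouring patch in that temperature window; failing that, stay."""
    window = sea.ocean & (sea.SST > 10.0) & (sea.SST < 14.0)
    y0, x0 = si.patch
    north = window.copy()
    north[: y0 + 1, :] = False
    ys, xs = np.nonzero(north)
    if ys.size:
        d2 = (ys - si.y) ** 2 + (xs - si.x) ** 2
        i = int(np.argmin(d2))
        ties = np.nonzero(d2 == d2[i])[0]
        j = int(ties[si.rng.randrange(ties.size)]) if ties.size > 1 else i
        si.y, si.x = float(ys[j]), float(xs[j])
        return si
    neigh = [
        (y0 + dy, x0 + dx)
        for dy, dx in NEIGHBOURS_4
        if sea.in_bounds(y0 + dy, x0 + dx) and window[y0 + dy, x0 + dx]
    ]
    if neigh:
        yy, xx = neigh[si.rng.randrange(len(neigh))]
        si.y, si.x = float(yy), float(xx)
    return si
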