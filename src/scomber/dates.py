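"""A 365-day model calendar (leap days ignored for cadence stability)."""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365
STEP_DAYS = 5
STEPS_PER_YEAR = DAYS_PER_YEAR // STEP_DAYS  # 73

MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
# day-of-year (1-based) on which each month starts
MONTH_STARTS = tuple(
    1 + int(np.cumsum((0,) + MONTH_LENGTHS)[m]) for m in range(12)
)  # (1, 32, 60, 91, 121, 152, 182, 213, 244, 274, 305, 335)

# named event dates (day of year, 1-based)
DOY_SPAWN_MIGRATION = 32    # Feb 1: spawning migration + maturation census
DOY_MATURATION = 32         # Feb 1
DOY_OGIVE_CENSUS = 41       # Feb 10
DOY_SPAWN_START = 60        # Mar 1: fecundity + spawning onset
DOY_Q1_JUV_CENSUS = 75      # Mar 16
DOY_FEED_MIGRATION = 121    # May 1: feeding migration + spawning-SSB census
DOY_EGG_CENSUS = 152        # Jun 1
DOY_SUMMER_CENSUS = 213     # Aug 1
DOY_OVERWINTER_MIGRATION = 274  # Oct 1
DOY_FAST_START = 305        # Nov 1: adults stop feeding
DOY_Q4_JUV_CENSUS = 327     # Nov 23
DOY_RECRUIT_CENSUS = 365    # Dec 31


_MONTH_OF_DOY = tuple(
    int(np.searchsorted(MONTH_STARTS, d, side="right"))
    for d in range(DAYS_PER_YEAR + 1)
)


def month_of_doy(doy: int) -> int:
    """1-based month containing 1-based day-of-year ``doy``."""
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise ValueError(f"day of year {doy} outside 1..{DAYS_PER_YEAR}")
    return _MONTH_OF_DOY[doy]


def doy_of(month: int, day: int) -> int:
    if not 1 <= month <= 12 or not 1 <= day <= MONTH_LENGTHS[month - 1]:
        raise ValueError(f"invalid month/day {month}/{day}")
    return MONTH_STARTS[month - 1] + day - 1


def step_days_covered(step: int) -> range:
    """1-based days-of-year covered by 0-based step index within a year."""
    if not 0 <= step < STEPS_PER_YEAR:
        raise ValueError(f"step {step} outside 0..{STEPS_PER_YEAR - 1}")
    d0 = step * STEP_DAYS + 1
    return range(d0, d0 + STEP_DAYS)


def step_containing(doy: int) -> int:
    return (doy - 1) // STEP_DAYS


def is_summer(doy: int) -> bool:
    """July/August window used for distribution summaries."""
    return MONTH_STARTS[6] <= doy < MONTH_STARTS[8]
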