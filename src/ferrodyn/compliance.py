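"""Dosing calendars, adherence patterns and their exposure timelines.

Two canonical non-adherence behaviours are modelled on top of a weekly
dosing calendar (by default 5 consecutive dosing days followed by 2 off
days):

* *poor quality of execution* — single doses missed uniformly at random
  over each treatment year;
* *drug holidays* — runs of consecutively missed doses at the start of each
  stratification block (1 year, 6 months, 2 months or 1 month).

Counting convention: a dosing year is 50 dosing weeks, so full adherence on
a 5 day/week schedule is exactly 250 doses per year, and the stratification
blocks contain 250, 125, 50 and 25 scheduled doses respectively.  This is
the arithmetic that makes the published missed-dose grids exact integers
(e.g. 40% missed over 1 year = 100 doses; 60% per 6-month block = 75).
Simulation time still flows in true hours; the calendar only fixes on which
days doses happen.

The observational adherence proxy CMPL is the fraction of a patient's
ferritin observations above 2500 ug/L; exposure corrected for adherence is
``TCss_av = Css_av * (1 - CMPL)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disease import ExposureTimeline
from .exceptions import DomainError
from .pk import InfusionRegimen, PKParameters, css_average

#: Dosing weeks per calendar year (250 doses/year at 5 days/week).
WEEKS_PER_YEAR = 50

#: Stratification period -> blocks per dosing year.
STRATIFICATIONS = {
    "1 year": 1,
    "6 months": 2,
    "2 months": 5,
    "1 month": 10,
}

#: Ferritin threshold (ug/L) separating moderate from severe iron overload.
SEVERITY_THRESHOLD = 2500.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3), matching the published counts."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class DosingCalendar:
    """Scheduled dose days and their taken/missed state.

    ``schedule`` holds calendar day indices (day 0 = treatment start) in
    strictly increasing order; ``taken`` is a parallel boolean array.
    """

    schedule: np.ndarray
    taken: np.ndarray
    dosing_days_per_week: int = 5

    def __post_init__(self) -> None:
        self.schedule = np.asarray(self.schedule, dtype=np.int64)
        self.taken = np.asarray(self.taken, dtype=bool)
        if self.schedule.ndim != 1 or self.taken.shape != self.schedule.shape:
            raise DomainError("schedule and taken must be parallel 1-D arrays")
        if self.schedule.size and np.any(np.diff(self.schedule) <= 0):
            raise DomainError("schedule must be strictly increasing")

    @property
    def n_scheduled(self) -> int:
        return int(self.schedule.size)

    @property
    def n_taken(self) -> int:
        return int(np.count_nonzero(self.taken))

    @property
    def n_missed(self) -> int:
        return self.n_scheduled - self.n_taken

    @property
    def doses_per_year(self) -> int:
        return WEEKS_PER_YEAR * self.dosing_days_per_week

    def year_blocks(self):
        """Slices of the dose sequence per dosing year (trailing part last)."""
        per_year = self.doses_per_year
        return [slice(i, min(i + per_year, self.n_scheduled))
                for i in range(0, self.n_scheduled, per_year)]

    def copy(self) -> "DosingCalendar":
        return DosingCalendar(self.schedule.copy(), self.taken.copy(),
                              self.dosing_days_per_week)

    def to_frame(self):
        """Serialisable table: (day_index, scheduled, taken)."""
        import pandas as pd

        return pd.DataFrame({"day_index": self.schedule,
                             "scheduled": 1,
                             "taken": self.taken.astype(int)})


@dataclass(frozen=True)
class ComplianceScenario:
    """One cell of the adherence scenario grid."""

    missed_fraction: float
    pattern: str = "random"  # "random" | "consecutive"
    stratification: str = "1 year"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missed_fraction <= 1.0:
            raise DomainError("missed_fraction must lie in [0, 1]")
        if self.pattern not in ("random", "consecutive"):
            raise DomainError(f"unknown pattern {self.pattern!r}")
        if self.stratification not in STRATIFICATIONS:
            raise DomainError(f"unknown stratification {self.stratification!r}")


@dataclass(frozen=True)
class AdherenceProxy:
    """Fraction of ferritin observations above the severity threshold."""

    cmpl: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cmpl <= 1.0:
            raise DomainError("cmpl must lie in [0, 1]")


def build_calendar(dosing_days_per_week: int = 5,
                   years: float = 1.0) -> DosingCalendar:
    """A fully adherent calendar covering ``years`` dosing years.

    One dosing year is 50 weeks; the number of dosing weeks is rounded to the
    nearest whole week.
    """
    if not years > 0:
        raise DomainError("years must be strictly positive")
    ddpw = int(dosing_days_per_week)
    if not 1 <= ddpw <= 7:
        raise DomainError("dosing_days_per_week must lie in 1..7")
    n_weeks = int(round(WEEKS_PER_YEAR * years))
    weeks = np.repeat(np.arange(n_weeks), ddpw)
    days = np.tile(np.arange(ddpw), n_weeks)
    schedule = weeks * 7 + days
    return DosingCalendar(schedule, np.ones(schedule.size, dtype=bool), ddpw)


def apply_random_missing(cal: DosingCalendar, missed_fraction: float,
                         seed: int = 0) -> DosingCalendar:
    """Miss single doses uniformly at random, year by year.

    Within each dosing year exactly ``round(missed_fraction * doses)`` doses
    are flipped to missed, drawn without replacement; deterministic for a
    given seed.
    """
    if not 0.0 <= missed_fraction <= 1.0:
        raise DomainError("missed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = cal.copy()
    for block in out.year_blocks():
        n = block.stop - block.start
        k = _round_half_away(missed_fraction * n)
        if k:
            miss = rng.choice(n, size=k, replace=False)
            out.taken[block.start + miss] = False
    return out


def apply_drug_holidays(cal: DosingCalendar, missed_fraction: float,
                        stratification: str = "1 year",
                        at_block_end: bool = False) -> DosingCalendar:
    """Miss consecutive doses at the start of each stratification block.

    The dose sequence is partitioned into blocks of
    ``doses_per_year / blocks_per_year`` scheduled doses (a shorter trailing
    block is handled pro-rata); within each block the first
    ``round(missed_fraction * block size)`` doses are missed.  Fully
    deterministic.  ``at_block_end=True`` places the holiday at the end of
    each block instead.
    """
    if not 0.0 <= missed_fraction <= 1.0:
        raise DomainError("missed_fraction must lie in [0, 1]")
    blocks_per_year = STRATIFICATIONS[stratification]
    block_size = cal.doses_per_year // blocks_per_year
    out = cal.copy()
    for start in range(0, out.n_scheduled, block_size):
        stop = min(start + block_size, out.n_scheduled)
        k = _round_half_away(missed_fraction * (stop - start))
        if k:
            if at_block_end:
                out.taken[stop - k:stop] = False
            else:
                out.taken[start:start + k] = False
    return out


def apply_scenario(cal: DosingCalendar,
                   scenario: ComplianceScenario) -> DosingCalendar:
    if scenario.pattern == "random":
        return apply_random_missing(cal, scenario.missed_fraction,
                                    scenario.seed)
    return apply_drug_holidays(cal, scenario.missed_fraction,
                               scenario.stratification)


def exposure_from_calendar(cal: DosingCalendar, regimen: InfusionRegimen,
                           pk: PKParameters) -> ExposureTimeline:
    """Daily piecewise-constant exposure timeline for a calendar.

    A taken-dose day carries the per-dosing-day average concentration
    ``dose / (CL(weight) * 24 h)``; missed and off days carry zero, so the
    full-adherence weekly mean reproduces the weekly ``Css_av`` exactly.
    Because the drug effect is linear in concentration, the sub-day PK shape
    does not alter the time-averaged effect.
    """
    level = css_average(pk, regimen, per_dosing_day=True).css_av
    if cal.n_scheduled == 0 or level == 0.0:
        return ExposureTimeline.constant(0.0)
    n_days = int(cal.schedule[-1]) + 1
    daily = np.zeros(n_days + 1)  # trailing zero day fixes the tail level
    daily[cal.schedule[cal.taken]] = level
    change = np.flatnonzero(np.r_[True, np.diff(daily) != 0])
    return ExposureTimeline(change * 24.0, daily[change])


def derive_cmpl(observations,
                threshold: float = SEVERITY_THRESHOLD) -> AdherenceProxy:
    """Adherence proxy: fraction of observations strictly above ``threshold``."""
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise DomainError("at least one observation is required")
    return AdherenceProxy(cmpl=float(np.mean(obs > threshold)))


def compliance_adjusted_exposure(css_av: float,
                                 proxy: AdherenceProxy) -> float:
    """Adherence-corrected exposure TCss_av = Css_av * (1 - CMPL)."""
    if css_av < 0:
        raise DomainError("css_av must be non-negative")
    return css_av * (1.0 - proxy.cmpl)
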