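"""Published aggregate counts of the Shanghai CRC screening programme.

The programme's accuracy tables can be reconstructed exactly from the
published margins: total tests, positives split by which track (RA, FIT,
both) was positive, and cancer counts split into screen-detected, missed
and interval cases.  This module ships those counts and derives the 2x2
confusion table for every strategy the margins determine.

Two cohorts are available: ``first_time`` (1,901,360 first-round tests) and
``multi_time`` (1,143,748 repeat-round tests).  Because the positives are
only split by RA-vs-any-FIT positivity, the first-FIT-specimen strategies
are *not* derivable from these margins; requesting one raises.

Known inconsistency in the published multi-time breakdown: the per-track
missed-case rows sum to 872 while the aggregate row reports 902 (a deficit
of 30, exposed as ``MULTI_TIME_MISSED_ROW_DEFICIT``).  Aggregate-row totals
are used for the all-tracks (parallel) table; per-track tables necessarily
use the breakdown numerators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import ConfusionTable, Strategy

__all__ = [
    "ScreeningCounts",
    "FIRST_TIME",
    "MULTI_TIME",
    "COHORTS",
    "MULTI_TIME_MISSED_ROW_DEFICIT",
    "confusion_table",
    "derivable_strategies",
]


@dataclass(frozen=True)
class ScreeningCounts:
    """Aggregate margins for one cohort of the screening programme.

    ``*_sd`` / ``*_missed`` give screen-detected and missed cancers within
    each positive track (RA only / FIT only / both positive); interval
    cancers all sit in the both-negative stratum.  ``screen_detected`` and
    ``missed`` are the published aggregate totals, which for the repeat
    rounds do not equal the sum of the breakdown rows.
    """

    total: int
    ra_only_pos: int
    fit_only_pos: int
    both_pos: int
    screen_detected: int
    missed: int
    interval: int
    ra_only_sd: int
    ra_only_missed: int
    fit_only_sd: int
    fit_only_missed: int
    both_sd: int
    both_missed: int

    @property
    def positives(self) -> int:
        return self.ra_only_pos + self.fit_only_pos + self.both_pos

    @property
    def cases(self) -> int:
        return self.screen_detected + self.missed + self.interval

    @property
    def breakdown_missed(self) -> int:
        return self.ra_only_missed + self.fit_only_missed + self.both_missed


FIRST_TIME = ScreeningCounts(
    total=1_901_360,
    ra_only_pos=162_476,
    fit_only_pos=225_751,
    both_pos=35_368,
    screen_detected=2_250,
    missed=1_530,
    interval=1_047,
    ra_only_sd=188,
    ra_only_missed=226,
    fit_only_sd=1_653,
    fit_only_missed=1_083,
    both_sd=409,
    both_missed=221,
)

MULTI_TIME = ScreeningCounts(
    total=1_143_748,
    ra_only_pos=131_716,
    fit_only_pos=137_315,
    both_pos=29_456,
    screen_detected=1_342,
    missed=902,
    interval=644,
    ra_only_sd=229,
    ra_only_missed=205,
    fit_only_sd=903,
    fit_only_missed=549,
    both_sd=210,
    both_missed=118,
)

COHORTS = {"first_time": FIRST_TIME, "multi_time": MULTI_TIME}

#: Published aggregate missed count minus the sum of the per-track rows in
#: the repeat-round cohort (902 - 872).
MULTI_TIME_MISSED_ROW_DEFICIT = MULTI_TIME.missed - MULTI_TIME.breakdown_missed


def derivable_strategies() -> tuple[Strategy, ...]:
    """Strategies whose 2x2 table the published margins determine."""
    return (
        Strategy.RA_ONLY,
        Strategy.FIT2_ONLY,
        Strategy.PARALLEL_RA_FIT2,
        Strategy.SERIAL_RA_FIT2,
    )


def confusion_table(counts: ScreeningCounts, strategy: Strategy) -> ConfusionTable:
    """Reconstruct the 2x2 table for one strategy from the margins.

    Cases = screen-detected + missed + interval (the aggregate rows); a
    strategy's true positives are the screen-detected and missed cancers in
    the tracks it calls positive, its false negatives the remaining cases.
    First-FIT-specimen strategies are not determined by the margins.
    """
    cases = counts.cases
    if strategy is Strategy.PARALLEL_RA_FIT2:
        pos = counts.positives
        tp = counts.screen_detected + counts.missed
    elif strategy is Strategy.RA_ONLY:
        pos = counts.ra_only_pos + counts.both_pos
        tp = (
            counts.ra_only_sd
            + counts.ra_only_missed
            + counts.both_sd
            + counts.both_missed
        )
    elif strategy is Strategy.FIT2_ONLY:
        pos = counts.fit_only_pos + counts.both_pos
        tp = (
            counts.fit_only_sd
            + counts.fit_only_missed
            + counts.both_sd
            + counts.both_missed
        )
    elif strategy is Strategy.SERIAL_RA_FIT2:
        pos = counts.both_pos
        tp = counts.both_sd + counts.both_missed
    else:
        raise ValueError(
            f"strategy {strategy.value} is not derivable from the published margins"
        )
    fn = cases - tp
    fp = pos - tp
    tn = counts.total - pos - fn
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
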