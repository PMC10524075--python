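"""Screening-episode model for a two-track colorectal-cancer triage programme.

A triage screening programme offers every participant a questionnaire-based
risk assessment (RA) and a two-specimen fecal immunochemical test (FIT);
anyone positive on either track is referred to colonoscopy.  This module
encodes

* the RA decision rule (any of three "major" history items, or at least two
  of six "minor" symptom/exposure items);
* the seven initial-test strategies the programme's accuracy can be
  evaluated under (each single test, and parallel/serial combinations of RA
  with the first or with either FIT specimen);
* the outcome-window classification that labels each screening episode as a
  screen-detected, missed, interval, or non-case, and its aggregation into a
  2x2 confusion table per strategy.

Cancer status is represented by the lag (in days) from screening to a
registry-confirmed diagnosis; an absent lag means no diagnosis within
follow-up.  A diagnosis within ``screen_detected_days`` of a positive screen
is screen-detected; later but within ``case_horizon_days`` it is a missed
case (positive screen, no timely work-up); any diagnosis within the horizon
after a negative screen is an interval case.  Episodes from repeat
participants are evaluated independently, one row per test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Iterable, Optional

__all__ = [
    "MAJOR_ITEMS",
    "MINOR_ITEMS",
    "RAProfile",
    "Strategy",
    "OutcomeClass",
    "OutcomeWindows",
    "DEFAULT_WINDOWS",
    "ScreeningEpisode",
    "ConfusionTable",
    "assess_risk",
    "combine_tests",
    "classify_outcome",
    "tabulate",
]

#: The three standalone high-risk history items.
MAJOR_ITEMS = (
    "major_cancer_history",
    "major_polyp_history",
    "major_family_crc",
)

#: The six symptom/exposure items, any two of which confer high risk.
MINOR_ITEMS = (
    "minor_constipation",
    "minor_diarrhea",
    "minor_mucus_bloody_stool",
    "minor_life_event",
    "minor_appendix",
    "minor_gallbladder",
)


@dataclass(frozen=True, slots=True)
class RAProfile:
    """Responses to the nine risk-assessment questionnaire items.

    Major items (any one suffices for a positive RA): history of any cancer,
    history of colorectal polyps, colorectal cancer in a first-degree
    relative.  Minor items (two or more suffice): chronic constipation,
    chronic diarrhea, mucus/bloody stool, a serious adverse life event,
    chronic appendicitis or appendectomy, chronic cholecystitis or
    cholecystectomy.
    """

    major_cancer_history: bool = False
    major_polyp_history: bool = False
    major_family_crc: bool = False
    minor_constipation: bool = False
    minor_diarrhea: bool = False
    minor_mucus_bloody_stool: bool = False
    minor_life_event: bool = False
    minor_appendix: bool = False
    minor_gallbladder: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, bool):
                raise TypeError(f"RA item {f.name!r} must be boolean, got {v!r}")


def assess_risk(profile: RAProfile) -> bool:
    """Apply the RA decision rule: any major item, or >= 2 minor items."""
    if any(getattr(profile, name) for name in MAJOR_ITEMS):
        return True
    return sum(getattr(profile, name) for name in MINOR_ITEMS) >= 2


class Strategy(enum.Enum):
    """The seven initial-test strategies.

    ``FIT2_ONLY`` is the two-specimen FIT, positive if *either* specimen is
    positive.  Parallel combinations are positive if any component is
    positive; serial combinations require RA positivity *and* FIT
    positivity.
    """

    RA_ONLY = "ra_only"
    FIT1_ONLY = "fit1_only"
    FIT2_ONLY = "fit2_only"
    PARALLEL_RA_FIT1 = "parallel_ra_fit1"
    SERIAL_RA_FIT1 = "serial_ra_fit1"
    PARALLEL_RA_FIT2 = "parallel_ra_fit2"
    SERIAL_RA_FIT2 = "serial_ra_fit2"


def combine_tests(
    strategy: Strategy,
    ra: bool,
    fit1: bool,
    fit2: Optional[bool],
    *,
    serial_both_specimens: bool = False,
) -> bool:
    """Positivity of the combined initial test under ``strategy``.

    Two-specimen FIT positivity means positive in either specimen.  For the
    serial RA + 2-specimen strategy the default follows that convention
    (RA AND (fit1 OR fit2)); ``serial_both_specimens=True`` instead requires
    positivity in both specimens (RA AND fit1 AND fit2), a stricter reading
    some programmes use.

    ``fit2`` may be ``None`` only for strategies that do not use the second
    specimen; otherwise a missing second specimen is an error (the
    programme mandates two specimens, so absence signals a data problem
    rather than a value to impute).
    """
    if not isinstance(strategy, Strategy):
        raise TypeError(f"unknown strategy: {strategy!r}")
    needs_fit2 = strategy in (
        Strategy.FIT2_ONLY,
        Strategy.PARALLEL_RA_FIT2,
        Strategy.SERIAL_RA_FIT2,
    )
    if needs_fit2 and fit2 is None:
        raise ValueError(f"strategy {strategy.value} requires a second FIT result")
    if strategy is Strategy.RA_ONLY:
        return ra
    if strategy is Strategy.FIT1_ONLY:
        return fit1
    if strategy is Strategy.FIT2_ONLY:
        return fit1 or bool(fit2)
    if strategy is Strategy.PARALLEL_RA_FIT1:
        return ra or fit1
    if strategy is Strategy.SERIAL_RA_FIT1:
        return ra and fit1
    if strategy is Strategy.PARALLEL_RA_FIT2:
        return ra or fit1 or bool(fit2)
    # SERIAL_RA_FIT2
    if serial_both_specimens:
        return ra and fit1 and bool(fit2)
    return ra and (fit1 or bool(fit2))


class OutcomeClass(enum.Enum):
    SCREEN_DETECTED = "screen_detected"
    MISSED = "missed"
    INTERVAL = "interval"
    NON_CASE = "non_case"


@dataclass(frozen=True, slots=True)
class OutcomeWindows:
    """Day windows defining the outcome classes.

    ``screen_detected_days`` — a diagnosis within this many days of a
    positive screen counts as screen-detected (default 90).
    ``case_horizon_days`` — diagnoses up to this lag count as cases at all
    (default 365, i.e. a one-year interval-cancer horizon).
    """

    screen_detected_days: int = 90
    case_horizon_days: int = 365

    def __post_init__(self) -> None:
        if self.screen_detected_days <= 0 or self.case_horizon_days <= 0:
            raise ValueError("outcome windows must be positive")
        if self.screen_detected_days >= self.case_horizon_days:
            raise ValueError("screen_detected_days must be < case_horizon_days")


DEFAULT_WINDOWS = OutcomeWindows()


def classify_outcome(
    initial_positive: bool,
    days_to_diagnosis: Optional[int],
    windows: OutcomeWindows = DEFAULT_WINDOWS,
) -> OutcomeClass:
    """Classify one episode given its positivity and diagnosis lag.

    No diagnosis, or a diagnosis beyond the case horizon, is a non-case.
    A positive screen with diagnosis within ``screen_detected_days`` is
    screen-detected; within the horizon but later, missed.  A negative
    screen with any diagnosis within the horizon is an interval case — the
    interval definition has no lower lag bound, so a negative screen
    diagnosed at, say, day 30 is still interval.
    """
    if days_to_diagnosis is None or days_to_diagnosis > windows.case_horizon_days:
        return OutcomeClass.NON_CASE
    if days_to_diagnosis < 0:
        raise ValueError("days_to_diagnosis must be >= 0")
    if not initial_positive:
        return OutcomeClass.INTERVAL
    if days_to_diagnosis <= windows.screen_detected_days:
        return OutcomeClass.SCREEN_DETECTED
    return OutcomeClass.MISSED


@dataclass(frozen=True, slots=True)
class ScreeningEpisode:
    """One screening event: RA result, two FIT results, diagnosis lag."""

    subject_id: str
    ra_positive: bool
    fit1_positive: bool
    fit2_positive: Optional[bool] = None
    days_to_diagnosis: Optional[int] = None
    wave_index: int = 1

    def __post_init__(self) -> None:
        if self.wave_index < 1:
            raise ValueError("wave_index must be >= 1")
        if self.days_to_diagnosis is not None and self.days_to_diagnosis < 0:
            raise ValueError("days_to_diagnosis must be >= 0")


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts for one strategy on one cohort."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for cell in (self.tp, self.fp, self.fn, self.tn):
            if cell < 0:
                raise ValueError("confusion-table cells must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp

    @property
    def cases(self) -> int:
        return self.tp + self.fn

    @property
    def non_cases(self) -> int:
        return self.fp + self.tn

    def scaled(self, factor: int) -> "ConfusionTable":
        return ConfusionTable(
            self.tp * factor, self.fp * factor, self.fn * factor, self.tn * factor
        )


def tabulate(
    episodes: Iterable[ScreeningEpisode],
    strategy: Strategy,
    windows: OutcomeWindows = DEFAULT_WINDOWS,
    *,
    serial_both_specimens: bool = False,
) -> ConfusionTable:
    """Aggregate a cohort into a 2x2 table under one strategy.

    A case is any episode whose outcome class is screen-detected, missed, or
    interval; positivity follows ``combine_tests``.  Screen-detected and
    missed cases are true positives (the screen flagged them), interval
    cases are false negatives, and non-cases fill the remaining cells.
    """
    tp = fp = fn = tn = 0
    n = 0
    for ep in episodes:
        n += 1
        pos = combine_tests(
            strategy,
            ep.ra_positive,
            ep.fit1_positive,
            ep.fit2_positive,
            serial_both_specimens=serial_both_specimens,
        )
        cls = classify_outcome(pos, ep.days_to_diagnosis, windows)
        if cls is OutcomeClass.NON_CASE:
            if pos:
                fp += 1
            else:
                tn += 1
        elif cls is OutcomeClass.INTERVAL:
            fn += 1
        else:  # screen-detected or missed: the screen was positive
            tp += 1
    if n == 0:
        raise ValueError("cannot tabulate an empty cohort")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
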