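"""Synthetic screening cohorts and meta-analysis study sets.

Two generators back the test pyramid:

``simulate_cohort`` emulates a triage screening round: each participant
is a cancer case with a small probability; the nine RA questionnaire items
are drawn at their marginal rates (odds-multiplied among cases) and pushed
through the actual RA decision rule; the two FIT specimens are drawn with
per-specimen sensitivity/specificity and a within-subject correlation
(with probability ``specimen_correlation`` a lesion sheds - or not - into
both specimens identically, otherwise the specimens are independent); and
the diagnosis lag is constructed so that screen-positive adherent cases
surface within the screen-detected window, screen-positive non-adherent
cases in the missed window, and screen-negative cases anywhere within the
one-year interval horizon.  Defaults emulate the operating point of a large
Chinese urban programme: prevalence 0.25%, per-specimen FIT sensitivity
0.57 / specificity 0.908 with correlation 0.46 (giving a two-specimen union
sensitivity near 0.70 and positivity near 14%), RA positivity near 10%,
and 60% colonoscopy adherence.

``simulate_study_set`` draws study-level (logit sens, logit spec) pairs
from the bivariate normal of the meta-analysis model, then binomial 2x2
cells, with study sizes log-uniform and per-study prevalence uniform over
configurable ranges.  Optional covariate effects shift the logits by
category, planting heterogeneity structure for meta-regression to find.

All randomness flows through ``numpy.random.default_rng`` (PCG64 - a
named, seedable, cross-platform generator) from the explicit ``seed``
field of the parameter object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    MAJOR_ITEMS,
    MINOR_ITEMS,
    ScreeningEpisode,
)
from .meta import StudyRecord

__all__ = [
    "CohortParams",
    "MetaParams",
    "simulate_cohort",
    "simulate_cohort_frame",
    "simulate_study_set",
    "episodes_from_frame",
    "union_sensitivity",
]

#: Column order of the cohort file format (and of simulate_cohort_frame).
RA_ITEM_COLUMNS = MAJOR_ITEMS + MINOR_ITEMS


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters for a synthetic screening cohort."""

    n_subjects: int = 100_000
    prevalence: float = 0.0025
    ra_item_rates: tuple[float, ...] = (
        0.005,  # any-cancer history
        0.02,  # colorectal-polyp history
        0.02,  # first-degree-relative CRC
        0.07,  # chronic constipation
        0.07,  # chronic diarrhea
        0.07,  # mucus / bloody stool
        0.07,  # adverse life event
        0.07,  # appendicitis / appendectomy
        0.07,  # cholecystitis / cholecystectomy
    )
    fit_sens_per_specimen: float = 0.57
    fit_spec_per_specimen: float = 0.908
    specimen_correlation: float = 0.46
    ra_case_enrichment: float = 1.8  # odds multiplier on each item among cases
    adherence_to_colonoscopy: float = 0.60
    #: mixture weights over (<=90 d, 91-365 d, >365 d) diagnosis lags
    lag_weights_adherent: tuple[float, float, float] = (1.0, 0.0, 0.0)
    lag_weights_nonadherent: tuple[float, float, float] = (0.0, 1.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            (self.prevalence, self.fit_sens_per_specimen, self.fit_spec_per_specimen,
             self.specimen_correlation, self.adherence_to_colonoscopy)
            + self.ra_item_rates
        )
        if len(self.ra_item_rates) != 9:
            raise ValueError("ra_item_rates must have exactly 9 entries")
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for w in (self.lag_weights_adherent, self.lag_weights_nonadherent):
            if len(w) != 3 or any(x < 0 for x in w) or not math.isclose(sum(w), 1.0):
                raise ValueError("lag weights must be 3 nonnegative values summing to 1")
        if self.ra_case_enrichment <= 0:
            raise ValueError("ra_case_enrichment must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")


def union_sensitivity(p: float, correlation: float) -> float:
    """Closed-form per-subject positivity of the 2-specimen union.

    With probability ``correlation`` both specimens share one Bernoulli(p)
    draw; otherwise they are independent: p_union = c p + (1-c)(1-(1-p)^2).
    """
    return correlation * p + (1.0 - correlation) * (1.0 - (1.0 - p) ** 2)


def _enriched(rate: float, odds_multiplier: float) -> float:
    odds = rate / (1.0 - rate) * odds_multiplier
    return odds / (1.0 + odds)


def _assess_risk_vector(items: np.ndarray) -> np.ndarray:
    """Vectorised RA rule: any major item, or >= 2 minor items.

    ``items`` is (n, 9) boolean in ``RA_ITEM_COLUMNS`` order; agreement with
    the scalar ``assess_risk`` is property-tested over all 512 profiles.
    """
    major = items[:, :3].any(axis=1)
    minor = items[:, 3:].sum(axis=1) >= 2
    return major | minor


def _draw_lags(rng, n: int, weights: Sequence[float]) -> np.ndarray:
    """Integer lags from the (<=90, 91-365, >365) bucket mixture."""
    bucket = rng.choice(3, size=n, p=np.asarray(weights, float))
    lags = np.empty(n, dtype=np.int64)
    lags[bucket == 0] = rng.integers(0, 91, size=int((bucket == 0).sum()))
    lags[bucket == 1] = rng.integers(91, 366, size=int((bucket == 1).sum()))
    lags[bucket == 2] = rng.integers(366, 731, size=int((bucket == 2).sum()))
    return lags


def simulate_cohort_frame(params: CohortParams) -> pd.DataFrame:
    """Simulate one screening round as a data frame (the file-format schema).

    Columns: subject_id, wave_index, the nine RA items (0/1), fit1, fit2,
    days_to_diagnosis (NaN = no diagnosis within follow-up).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    is_case = rng.random(n) < params.prevalence

    items = np.empty((n, 9), dtype=bool)
    for j, rate in enumerate(params.ra_item_rates):
        case_rate = _enriched(rate, params.ra_case_enrichment)
        p = np.where(is_case, case_rate, rate)
        items[:, j] = rng.random(n) < p
    ra = _assess_risk_vector(items)

    p_pos = np.where(is_case, params.fit_sens_per_specimen, 1.0 - params.fit_spec_per_specimen)
    shared = rng.random(n) < params.specimen_correlation
    base = rng.random(n) < p_pos
    d1 = rng.random(n) < p_pos
    d2 = rng.random(n) < p_pos
    fit1 = np.where(shared, base, d1)
    fit2 = np.where(shared, base, d2)

    screen_pos = ra | fit1 | fit2  # the programme's parallel rule
    adherent = rng.random(n) < params.adherence_to_colonoscopy

    days = np.full(n, np.nan)
    idx_pos_adh = np.flatnonzero(is_case & screen_pos & adherent)
    idx_pos_non = np.flatnonzero(is_case & screen_pos & ~adherent)
    idx_neg = np.flatnonzero(is_case & ~screen_pos)
    days[idx_pos_adh] = _draw_lags(rng, len(idx_pos_adh), params.lag_weights_adherent)
    days[idx_pos_non] = _draw_lags(rng, len(idx_pos_non), params.lag_weights_nonadherent)
    days[idx_neg] = rng.integers(0, 366, size=len(idx_neg))

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:07d}" for i in range(n)],
            "wave_index": np.ones(n, dtype=np.int64),
        }
    )
    for j, col in enumerate(RA_ITEM_COLUMNS):
        frame[col] = items[:, j].astype(np.int8)
    frame["fit1"] = fit1.astype(np.int8)
    frame["fit2"] = fit2.astype(np.int8)
    frame["days_to_diagnosis"] = days
    return frame


def episodes_from_frame(frame: pd.DataFrame) -> list[ScreeningEpisode]:
    """Typed episodes from a cohort frame (applies the RA rule to the items)."""
    items = frame[list(RA_ITEM_COLUMNS)].to_numpy(dtype=bool)
    ra = _assess_risk_vector(items)
    fit1 = frame["fit1"].to_numpy(dtype=bool)
    fit2 = frame["fit2"].to_numpy(dtype=bool)
    days = frame["days_to_diagnosis"].to_numpy(dtype=float)
    waves = frame["wave_index"].to_numpy(dtype=np.int64)
    ids = frame["subject_id"].astype(str).to_numpy()
    return [
        ScreeningEpisode(
            subject_id=ids[i],
            ra_positive=bool(ra[i]),
            fit1_positive=bool(fit1[i]),
            fit2_positive=bool(fit2[i]),
            days_to_diagnosis=None if math.isnan(days[i]) else int(days[i]),
            wave_index=int(waves[i]),
        )
        for i in range(len(frame))
    ]


def simulate_cohort(params: CohortParams) -> list[ScreeningEpisode]:
    """Simulate one screening round as typed episodes."""
    return episodes_from_frame(simulate_cohort_frame(params))


@dataclass(frozen=True)
class MetaParams:
    """Generating parameters for a synthetic meta-analysis study set.

    The default operating point mirrors the overall pooled accuracy of
    published FIT/RA screening studies (sens ~0.73, spec ~0.92) with
    substantial between-study spread and the usual negative logit-scale
    correlation.  Per-study disease margins are case-enriched (prevalence
    drawn from ``prevalence_range``) so that sensitivities are estimable at
    moderate study sizes, as in diagnostic-accuracy study collections.
    """

    n_studies: int = 103
    mu_sens: float = math.log(0.73 / 0.27)
    mu_spec: float = math.log(0.92 / 0.08)
    tau_sens: float = 0.4
    tau_spec: float = 0.5
    rho: float = -0.3
    study_size_range: tuple[int, int] = (500, 5000)  # log-uniform
    prevalence_range: tuple[float, float] = (0.1, 0.3)
    covariate_effects: Optional[Mapping[str, Mapping[str, tuple[float, float]]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies <= 0:
            raise ValueError("n_studies must be positive")
        if self.tau_sens < 0 or self.tau_spec < 0:
            raise ValueError("tau must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.study_size_range[0] < 10 or self.study_size_range[0] > self.study_size_range[1]:
            raise ValueError("study sizes must be >= 10 and ordered")
        lo, hi = self.prevalence_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("prevalence range must lie in (0, 1) and be ordered")


def simulate_study_set(params: MetaParams) -> list[StudyRecord]:
    """Draw studies from the bivariate logit-normal data-generating model."""
    rng = np.random.default_rng(params.seed)
    k = params.n_studies
    cov = np.array(
        [
            [params.tau_sens**2, params.rho * params.tau_sens * params.tau_spec],
            [params.rho * params.tau_sens * params.tau_spec, params.tau_spec**2],
        ]
    )
    logits = rng.multivariate_normal([params.mu_sens, params.mu_spec], cov, size=k)

    covariates: list[dict[str, str]] = [dict() for _ in range(k)]
    if params.covariate_effects:
        for name, cats in params.covariate_effects.items():
            labels = sorted(cats)
            assign = rng.integers(0, len(labels), size=k)
            for i in range(k):
                label = labels[assign[i]]
                covariates[i][name] = label
                shift = cats[label]
                logits[i, 0] += shift[0]
                logits[i, 1] += shift[1]

    lo, hi = params.study_size_range
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), size=k)).astype(np.int64)
    prev = rng.uniform(*params.prevalence_range, size=k)
    sens = 1.0 / (1.0 + np.exp(-logits[:, 0]))
    spec = 1.0 / (1.0 + np.exp(-logits[:, 1]))

    records = []
    for i in range(k):
        n_dis = int(rng.binomial(sizes[i], prev[i]))
        n_non = int(sizes[i]) - n_dis
        tp = int(rng.binomial(n_dis, sens[i])) if n_dis else 0
        tn = int(rng.binomial(n_non, spec[i])) if n_non else 0
        records.append(
            StudyRecord(
                study_id=f"study_{i:03d}",
                tp=tp,
                fn=n_dis - tp,
                tn=tn,
                fp=n_non - tn,
                covariates=covariates[i],
            )
        )
    return records
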