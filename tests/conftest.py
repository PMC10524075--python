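import math

import numpy as np
import pytest

from crcscreen import (
    CohortParams,
    MetaParams,
    ScreeningEpisode,
    simulate_study_set,
)


@pytest.fixture(scope="session")
def toy_cohort():
    """Six hand-built episodes: one screen-detected, one missed, one
    interval case, three non-cases (one false positive)."""
    return [
        ScreeningEpisode("a", ra_positive=True, fit1_positive=False,
                         fit2_positive=False, days_to_diagnosis=60),
        ScreeningEpisode("b", ra_positive=False, fit1_positive=True,
                         fit2_positive=False, days_to_diagnosis=200),
        ScreeningEpisode("c", ra_positive=False, fit1_positive=False,
                         fit2_positive=False, days_to_diagnosis=300),
        ScreeningEpisode("d", ra_positive=False, fit1_positive=False,
                         fit2_positive=False),
        ScreeningEpisode("e", ra_positive=True, fit1_positive=False,
                         fit2_positive=False),
        ScreeningEpisode("f", ra_positive=False, fit1_positive=False,
                         fit2_positive=True, days_to_diagnosis=500),
    ]


def random_cohort(rng: np.random.Generator, n: int = 400) -> list[ScreeningEpisode]:
    """Random episodes exercising every positivity pattern and lag regime."""
    eps = []
    for i in range(n):
        days = None
        if rng.random() < 0.3:
            days = int(rng.integers(0, 800))
        eps.append(
            ScreeningEpisode(
                subject_id=f"r{i}",
                ra_positive=bool(rng.random() < 0.3),
                fit1_positive=bool(rng.random() < 0.3),
                fit2_positive=bool(rng.random() < 0.3),
                days_to_diagnosis=days,
            )
        )
    return eps


@pytest.fixture(scope="session")
def homogeneous_studies():
    """20 identical studies: sens 0.76, spec 0.93, no between-study spread."""
    from crcscreen import StudyRecord

    return [
        StudyRecord(f"s{i}", tp=76, fn=24, tn=93, fp=7) for i in range(20)
    ]


@pytest.fixture(scope="session")
def heterogeneous_studies():
    """100 studies from the bivariate logit-normal generator."""
    params = MetaParams(
        n_studies=100,
        mu_sens=math.log(0.76 / 0.24),
        mu_spec=math.log(0.92 / 0.08),
        tau_sens=0.4,
        tau_spec=0.5,
        rho=-0.3,
        study_size_range=(1500, 2500),
        seed=11,
    )
    return simulate_study_set(params)


@pytest.fixture(scope="session")
def small_cohort_params():
    return CohortParams(n_subjects=50_000, seed=5)
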