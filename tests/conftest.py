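"""Shared fixtures: hand-built micro-surveys and small synthetic surveys."""

from __future__ import annotations

import numpy as np
import pytest

from matdenom import (
    PregnancyOutcome,
    PregnancyRecord,
    Respondent,
    Sex,
    SiblingRecord,
    SimulationParams,
    Survey,
    cmc,
    generate_survey,
)
from matdenom.data_model import DeathTiming

INTERVIEW = cmc(2022, 7)  # 1471


def make_respondent(
    rid: str,
    age_years: float = 30,
    weight: float = 1.0,
    cluster: str = "C1",
    stratum: str = "S1",
    interview: int = INTERVIEW,
) -> Respondent:
    return Respondent(
        id=rid,
        weight=weight,
        cluster=cluster,
        stratum=stratum,
        dob_cmc=interview - int(round(age_years * 12)),
        interview_cmc=interview,
    )


def make_dead_sister(
    rid: str,
    dob_cmc: int,
    dod_cmc: int,
    timing=DeathTiming.DURING_DELIVERY,
    violent: bool = False,
) -> SiblingRecord:
    return SiblingRecord(
        respondent_id=rid,
        sex=Sex.FEMALE,
        alive=False,
        dob_cmc=dob_cmc,
        dod_cmc=dod_cmc,
        death_timing=timing,
        violent_or_accidental=violent,
    )


def make_live_birth(rid: str, end_cmc: int) -> PregnancyRecord:
    return PregnancyRecord(rid, end_cmc, 9, PregnancyOutcome.LIVE_BIRTH)


@pytest.fixture(scope="session")
def tiny_params() -> SimulationParams:
    """A small but estimable synthetic survey: 6 clusters, 120 women."""
    return SimulationParams(
        n_strata=2,
        clusters_per_stratum=3,
        respondents_per_cluster=20,
        prm_x=(0.004, 0.005, 0.006, 0.008, 0.010, 0.012, 0.014),  # x10 so deaths exist at n=120
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_survey(tiny_params) -> Survey:
    return generate_survey(tiny_params)


@pytest.fixture(scope="session")
def medium_survey() -> Survey:
    """~1250 respondents at the default study conditions."""
    return generate_survey(SimulationParams(seed=5))


def month_enumeration_exposure(dob: int, dod, start: int, end: int) -> list[float]:
    """Independent person-years oracle: walk every month of the window.

    Pure-Python reimplementation of the exposure definition; counts months
    and divides by 12 once per group.
    """
    counts = [0] * 7
    for m in range(start, end + 1):
        if m < dob:
            continue
        if dod is not None and m > dod:
            continue
        age = m - dob
        if 180 <= age <= 599:
            counts[(age - 180) // 60] += 1
    return [c / 12.0 for c in counts]
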