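"""Pregnancy-outcome classification and denominator adjustment factors.

Maternal mortality ratios conventionally divide by live births. Because
morbidity and mortality can follow any pregnancy outcome, the denominator can
instead be *total births* (live births + stillbirths) or *total pregnancies*
(total births + miscarriages/induced abortions). The conversion happens
through age-specific adjustment factors

    A_x(total births)      = (LB_x + SB_x) / LB_x
    A_x(total pregnancies) = (LB_x + SB_x + MA_x) / LB_x

where LB_x, SB_x, MA_x are sampling-weighted counts of live births,
stillbirths, and miscarriages/abortions reported in the five-year calendar
window before each interview, by mother's five-year age group x. Surveys
record no gestational age in weeks, so a stillbirth is operationalised as a
pregnancy loss at seven or more months of gestation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .agegroups import AgeGroupTable, N_AGE_GROUPS, age_group_index_from_months
from .data_model import PregnancyOutcome, PregnancyRecord, Survey
from .demographic_time import Window
from .errors import EmptyDistributionError, UndefinedFactorError

__all__ = [
    "OutcomeClass",
    "Scenario",
    "OutcomeDistribution",
    "classify_outcome",
    "outcome_distribution",
    "adjustment_factors",
]

#: Gestation duration (completed months) at or above which a pregnancy loss
#: counts as a stillbirth. Losses below it — including a recorded duration of
#: exactly 6 months, which the survey instruments leave unassigned — pool
#: into the miscarriage/abortion class.
STILLBIRTH_MIN_MONTHS = 7


class OutcomeClass(str, enum.Enum):
    """Collapsed outcome classes used to build adjustment factors."""

    LIVE_BIRTH = "live_birth"
    STILLBIRTH = "stillbirth"
    MISCARRIAGE_OR_ABORTION = "miscarriage_or_abortion"


class Scenario(str, enum.Enum):
    """Denominator scenario for a mortality ratio."""

    LIVE_BIRTHS = "live_births"
    TOTAL_BIRTHS = "total_births"
    TOTAL_PREGNANCIES = "total_pregnancies"


def classify_outcome(record: PregnancyRecord) -> OutcomeClass:
    """Collapse a reported pregnancy outcome into LB / SB / MSC-AB.

    A live birth maps to itself; any non-live outcome at seven or more
    months of gestation is a stillbirth; any non-live outcome below seven
    months (miscarriage, induced abortion, or an unclassified loss) is
    miscarriage-or-abortion.
    """
    return _classify(record.outcome, record.duration_months)


def _classify(outcome, duration_months) -> OutcomeClass:
    if PregnancyOutcome(outcome) is PregnancyOutcome.LIVE_BIRTH:
        return OutcomeClass.LIVE_BIRTH
    if int(duration_months) >= STILLBIRTH_MIN_MONTHS:
        return OutcomeClass.STILLBIRTH
    return OutcomeClass.MISCARRIAGE_OR_ABORTION


def classify_outcomes_frame(pregnancies: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_outcome` over a pregnancies table."""
    live = pregnancies["outcome"] == PregnancyOutcome.LIVE_BIRTH.value
    late = pregnancies["duration_months"].astype(int) >= STILLBIRTH_MIN_MONTHS
    out = np.where(
        live,
        OutcomeClass.LIVE_BIRTH.value,
        np.where(late, OutcomeClass.STILLBIRTH.value, OutcomeClass.MISCARRIAGE_OR_ABORTION.value),
    )
    return pd.Series(out, index=pregnancies.index)


@dataclass
class OutcomeDistribution:
    """Sampling-weighted pregnancy-outcome counts by mother's age group.

    ``lb``/``sb``/``msc_ab`` hold weighted counts of live births,
    stillbirths, and miscarriages-or-abortions whose pregnancy ended inside
    the mother's calendar window at a maternal age of 15-49.
    """

    lb: AgeGroupTable
    sb: AgeGroupTable
    msc_ab: AgeGroupTable
    window: Window

    @property
    def total(self) -> float:
        return self.lb.sum() + self.sb.sum() + self.msc_ab.sum()

    def proportions(self) -> dict[str, float]:
        """Overall weighted shares of the three classes (they sum to 1)."""
        tot = self.total
        if tot <= 0:
            raise EmptyDistributionError("no weighted pregnancy outcomes in the window")
        return {
            OutcomeClass.LIVE_BIRTH.value: self.lb.sum() / tot,
            OutcomeClass.STILLBIRTH.value: self.sb.sum() / tot,
            OutcomeClass.MISCARRIAGE_OR_ABORTION.value: self.msc_ab.sum() / tot,
        }

    def to_frame(self) -> pd.DataFrame:
        """Group x outcome table of weighted counts and within-total proportions."""
        tot = self.total
        df = pd.DataFrame(
            {
                "age_group": list(self.lb.to_dict()),
                "live_birth": self.lb.values,
                "stillbirth": self.sb.values,
                "miscarriage_or_abortion": self.msc_ab.values,
            }
        )
        for col in ("live_birth", "stillbirth", "miscarriage_or_abortion"):
            df[f"prop_{col}"] = df[col] / tot if tot > 0 else np.nan
        return df

    def __add__(self, other: "OutcomeDistribution") -> "OutcomeDistribution":
        win = Window(
            min(self.window.start_cmc, other.window.start_cmc),
            max(self.window.end_cmc, other.window.end_cmc),
            label=self.window.label,
        )
        return OutcomeDistribution(
            self.lb + other.lb, self.sb + other.sb, self.msc_ab + other.msc_ab, win
        )


def outcome_distribution(survey: Survey, window_years: int = 5) -> OutcomeDistribution:
    """Weighted outcome distribution over each respondent's calendar window.

    Each pregnancy ending within ``window_years`` years before its
    respondent's interview (interview month excluded) contributes the
    respondent's sampling weight to the classified outcome's count, indexed
    by the mother's age group at the pregnancy end; maternal ages outside
    15-49 are excluded.
    """
    preg = survey.pregnancies
    if preg.empty:
        raise EmptyDistributionError("survey has no pregnancy records")
    resp = survey.respondents.set_index("resp_id")
    mother = resp.loc[preg["resp_id"]]

    end = preg["end_cmc"].to_numpy(dtype=np.int64)
    interview = mother["interview_cmc"].to_numpy(dtype=np.int64)
    dob = mother["dob_cmc"].to_numpy(dtype=np.int64)
    weight = mother["weight"].to_numpy(dtype=float)

    start = interview - 12 * window_years
    in_window = (end >= start) & (end <= interview - 1)
    group = age_group_index_from_months(end - dob)
    keep = in_window & (group >= 0)
    if not keep.any():
        raise EmptyDistributionError(
            f"no pregnancy outcomes inside any respondent's {window_years}-year window"
        )

    cls = classify_outcomes_frame(preg).to_numpy()
    tables = {}
    for oc in OutcomeClass:
        mask = keep & (cls == oc.value)
        tables[oc] = AgeGroupTable(
            np.bincount(group[mask], weights=weight[mask], minlength=N_AGE_GROUPS)
        )

    window = Window(int(start.min()), int(interview.max() - 1), label=f"calendar-{window_years}y")
    return OutcomeDistribution(
        tables[OutcomeClass.LIVE_BIRTH],
        tables[OutcomeClass.STILLBIRTH],
        tables[OutcomeClass.MISCARRIAGE_OR_ABORTION],
        window,
    )


def adjustment_factors(
    dist: OutcomeDistribution,
    scenario: Scenario | str,
    required_groups: np.ndarray | None = None,
    warn_empty: bool = True,
) -> AgeGroupTable:
    """Age-specific denominator adjustment factors A_x for a scenario.

    live_births -> A_x = 1; total_births -> (LB_x+SB_x)/LB_x;
    total_pregnancies -> (LB_x+SB_x+MA_x)/LB_x. Every factor is >= 1.

    Groups with no in-window pregnancies at all get the neutral factor 1
    (with a warning): they contribute nothing to the fertility numerator
    either. A group with zero live births but non-live outcomes has an
    undefined factor; that raises only when the group is ``required``
    downstream (defaults to all groups).
    """
    scenario = Scenario(scenario)
    lb, sb, ma = dist.lb.values, dist.sb.values, dist.msc_ab.values
    if scenario is Scenario.LIVE_BIRTHS:
        return AgeGroupTable(np.ones(N_AGE_GROUPS))

    numer = lb + sb if scenario is Scenario.TOTAL_BIRTHS else lb + sb + ma
    empty = (lb + sb + ma) == 0
    undefined = (lb == 0) & ~empty
    if required_groups is None:
        required = np.ones(N_AGE_GROUPS, dtype=bool)
    else:
        required = np.asarray(required_groups, dtype=bool)
    bad = undefined & required
    if bad.any():
        labels = [lbl for lbl, b in zip(dist.lb.to_dict(), bad) if b]
        raise UndefinedFactorError(
            f"zero live births but non-live outcomes in group(s) {labels}; "
            f"{scenario.value} factor undefined"
        )
    if warn_empty and empty.any():
        labels = [lbl for lbl, e in zip(dist.lb.to_dict(), empty) if e]
        warnings.warn(
            f"no in-window pregnancies in group(s) {labels}; using neutral factor 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(lb > 0, numer / np.where(lb > 0, lb, 1.0), 1.0)
    return AgeGroupTable(a)
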