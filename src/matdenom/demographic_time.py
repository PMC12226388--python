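"""Century-month-code arithmetic, reference windows, and person-years of exposure.

All dates in the pipeline are century-month codes (CMC), the household-survey
convention: months elapsed since January 1900, with January 1900 = 1, i.e.
``cmc = 12*(year - 1900) + month``. CMC data carry no sub-month precision, so
exposure is attributed month by month at 1/12 year per month.

Conventions (recorded here once, applied everywhere):

* A reference window of ``y`` years ends the month *before* the interview
  month — the interview month is excluded, since it is only partially
  observed.
* The month of death counts as exposed (the person was alive for part of it).
* Person-months at completed ages outside 15-49 years contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agegroups import (
    AgeGroupTable,
    GROUP_WIDTH_MONTHS,
    MAX_AGE_MONTHS,
    MIN_AGE_MONTHS,
    N_AGE_GROUPS,
)

__all__ = [
    "cmc",
    "cmc_to_year_month",
    "Window",
    "reference_window",
    "age_group_at",
    "person_years",
    "person_months_between",
    "person_months_by_group",
]


def cmc(year: int, month: int) -> int:
    """Century-month code of a calendar (year, month); (1900, 1) -> 1."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return 12 * (year - 1900) + month


def cmc_to_year_month(code: int) -> tuple[int, int]:
    """Inverse of :func:`cmc`: recover (year, month) from a century-month code."""
    year, month0 = divmod(int(code) - 1, 12)
    return 1900 + year, month0 + 1


@dataclass(frozen=True)
class Window:
    """A closed interval of months [start_cmc, end_cmc], both inclusive."""

    start_cmc: int
    end_cmc: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_cmc > self.end_cmc:
            raise ValueError(f"window start {self.start_cmc} after end {self.end_cmc}")

    @property
    def months(self) -> int:
        return self.end_cmc - self.start_cmc + 1

    @property
    def years(self) -> float:
        return self.months / 12.0

    def contains(self, code) -> np.ndarray | bool:
        c = np.asarray(code)
        return (c >= self.start_cmc) & (c <= self.end_cmc)


def reference_window(interview_cmc: int, years: int, label: str = "") -> Window:
    """The ``years``-year window ending the month before the interview.

    The interview month itself is excluded, so the window spans exactly
    ``12*years`` months: ``[interview - 12*years, interview - 1]``.
    """
    if years <= 0:
        raise ValueError(f"window length must be positive, got {years}")
    return Window(interview_cmc - 12 * years, interview_cmc - 1, label=label)


def age_group_at(dob_cmc: int, event_cmc: int) -> int | None:
    """Five-year age-group index (0 = 15-19 .. 6 = 45-49) at an event, or None.

    Age is completed months ``event_cmc - dob_cmc``; returns None when the
    age falls outside 15-49 completed years.
    """
    a = int(event_cmc) - int(dob_cmc)
    if a < 0:
        raise ValueError(f"event at cmc {event_cmc} precedes birth at {dob_cmc}")
    if a < MIN_AGE_MONTHS or a > MAX_AGE_MONTHS:
        return None
    return (a - MIN_AGE_MONTHS) // GROUP_WIDTH_MONTHS


def person_months_between(dob_cmc, dod_cmc, start_cmc, end_cmc) -> np.ndarray:
    """Exact integer months lived in each age group within [start, end].

    Vectorised over individuals: all arguments broadcast to (N,);
    ``dod_cmc`` is float with NaN for the living. Returns an int64 array
    (N, 7). A month m counts toward group g iff start <= m <= end,
    m >= dob, m <= dod (death month inclusive) and the completed age at m
    lies in group g's range. Computed by closed-form interval overlap,
    which equals month-by-month enumeration exactly.
    """
    dob, dod, start, end = np.broadcast_arrays(
        np.asarray(dob_cmc, dtype=np.int64),
        np.asarray(dod_cmc, dtype=float),
        np.asarray(start_cmc, dtype=np.int64),
        np.asarray(end_cmc, dtype=np.int64),
    )
    dob = np.atleast_1d(dob)
    dod = np.atleast_1d(dod)
    start = np.atleast_1d(start)
    end = np.atleast_1d(end)
    n = dob.shape[0]

    # Last month of presence: end of window, capped by death month.
    hi_alive = end.copy()
    has_dod = ~np.isnan(dod)
    hi_alive[has_dod] = np.minimum(hi_alive[has_dod], dod[has_dod].astype(np.int64))
    lo_alive = np.maximum(dob, start)

    out = np.zeros((n, N_AGE_GROUPS), dtype=np.int64)
    for g in range(N_AGE_GROUPS):
        g_lo = dob + MIN_AGE_MONTHS + g * GROUP_WIDTH_MONTHS
        g_hi = g_lo + GROUP_WIDTH_MONTHS - 1
        lo = np.maximum(lo_alive, g_lo)
        hi = np.minimum(hi_alive, g_hi)
        out[:, g] = np.maximum(hi - lo + 1, 0)
    return out


def person_months_by_group(dob_cmc, dod_cmc, window: Window) -> np.ndarray:
    """:func:`person_months_between` against a single shared :class:`Window`."""
    return person_months_between(dob_cmc, dod_cmc, window.start_cmc, window.end_cmc)


def person_years(dob_cmc: int, dod_cmc: int | None, window: Window) -> AgeGroupTable:
    """Years of exposure by five-year age group within the window.

    Each month present and aged 15-49 contributes 1/12 year to its group;
    ``dod_cmc`` is None for a person alive through the window.
    """
    dod = np.array([np.nan if dod_cmc is None else float(dod_cmc)])
    months = person_months_by_group(np.array([dob_cmc]), dod, window)[0]
    return AgeGroupTable(months / 12.0)
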