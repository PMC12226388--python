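"""Sisterhood-method mortality ratios: rates, fertility, and ratio assembly.

The estimator follows the standard survey implementation. Over a seven-year
window before each interview, sampling-weighted maternal deaths MD_x and
pregnancy-related deaths PrD_x among respondents' sisters are divided by the
sisters' person-years of exposure E_Sx within five-year age groups x, giving
age-specific mortality rates. These are composited with the weighted
respondent age distribution C_x and divided by the general fertility rate:

    MMR  = sum_x (MD_x / E_Sx) C_x / GFR * 100,000
    PRMR = sum_x (PrD_x / E_Sx) C_x / GFR * 100,000
    GFR  = sum_x (B_x / E_Rx) C_x A_x

B_x are respondents' own live births and E_Rx their exposure over the same
window; A_x are the denominator adjustment factors (all 1 for the
conventional live-birth denominator; see :mod:`matdenom.adjustment`).

A death is *pregnancy-related* when it occurred during pregnancy, during
delivery, or within two months of the end of the pregnancy, irrespective of
cause; it is *maternal* when additionally not due to violence or accident.
(This survey definition is wider than ICD-11, which also excludes other
incidental causes.)

Internally every input is aggregated per sampling cluster first, so the
delete-one-cluster jackknife can recompute the full ratio for each replicate
by subtracting one cluster's row of totals instead of re-running the
pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegroups import AgeGroupTable, N_AGE_GROUPS, age_group_index_from_months
from .adjustment import (
    OutcomeClass,
    OutcomeDistribution,
    Scenario,
    adjustment_factors,
    classify_outcomes_frame,
)
from .data_model import (
    PREGNANCY_RELATED_TIMINGS,
    PregnancyOutcome,
    Sex,
    SiblingRecord,
    Survey,
    require_valid,
)
from .demographic_time import Window, person_months_between
from .errors import CapabilityError, DegenerateInputError
from .variance import Z_95, jackknife_from_replicates

__all__ = [
    "Metric",
    "DeathClass",
    "EstimateConfig",
    "MortalityInputs",
    "FertilityInputs",
    "RatioEstimate",
    "classify_death",
    "mortality_inputs",
    "fertility_inputs",
    "gfr",
    "mortality_ratio",
    "estimate",
    "aggregate",
    "estimate_from_aggregates",
    "ClusterAggregates",
]

PER = 100_000.0


class Metric(str, enum.Enum):
    MMR = "MMR"
    PRMR = "PRMR"

    @classmethod
    def coerce(cls, value) -> "Metric":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


class DeathClass(str, enum.Enum):
    MATERNAL_AND_PREGNANCY_RELATED = "maternal_and_pregnancy_related"
    PREGNANCY_RELATED_ONLY = "pregnancy_related_only"
    NEITHER = "neither"


@dataclass
class EstimateConfig:
    """Run configuration: window lengths and estimator conventions.

    mortality_years / fertility_years: length of the pre-interview window
    for sibling deaths/exposure and for respondents' births/exposure (both 7
    by convention). calendar_years: window for the pregnancy-outcome
    distribution behind A_x (5 by convention). include_interview_month:
    windows normally end the month before the interview; set True to end at
    the interview month instead. drop_failing_replicates: on a jackknife
    replicate where the ratio is undefined, drop the replicate (and count
    it) instead of raising.
    """

    mortality_years: int = 7
    fertility_years: int = 7
    calendar_years: int = 5
    include_interview_month: bool = False
    drop_failing_replicates: bool = False

    def window_bounds(self, interview_cmc, years: int):
        """(start, end) arrays of the years-long window per interview date."""
        iv = np.asarray(interview_cmc, dtype=np.int64)
        end = iv if self.include_interview_month else iv - 1
        return end - 12 * years + 1, end

    @classmethod
    def from_yaml(cls, path) -> "EstimateConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MortalityInputs:
    """Numerator-side inputs: weighted death counts, sister exposure, C_x.

    ``md`` is None when the survey lacks violence/accident flags (the
    survey then supports PRMR only).
    """

    md: AgeGroupTable | None
    prd: AgeGroupTable
    e_s: AgeGroupTable
    c: AgeGroupTable
    window_years: int = 7


@dataclass
class FertilityInputs:
    """Denominator-side inputs: respondents' live births, exposure, A_x."""

    b: AgeGroupTable
    e_r: AgeGroupTable
    a: AgeGroupTable
    window_years: int = 7


@dataclass
class RatioEstimate:
    """A mortality ratio per 100,000 under one denominator scenario."""

    metric: str
    scenario: Scenario
    value: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_clusters: int | None = None
    n_dropped_replicates: int = 0
    replicate_values: list[float] = field(default_factory=list)


def classify_death(rec: SiblingRecord) -> DeathClass:
    """Classify a dead sister's death for the MMR/PRMR numerators.

    Pregnancy-related: timing reported as during pregnancy, during delivery,
    or within two months postpartum. Maternal: pregnancy-related and not
    violent/accidental. Raises on living or male siblings, and raises
    :class:`CapabilityError` if the violence flag is missing for a
    pregnancy-related death (the maternal subset is then unknowable).
    """
    if rec.alive:
        raise ValueError("classify_death called on a living sibling")
    if Sex(rec.sex) is not Sex.FEMALE:
        raise ValueError("classify_death called on a male sibling")
    timing = getattr(rec.death_timing, "value", rec.death_timing)
    if timing not in PREGNANCY_RELATED_TIMINGS:
        return DeathClass.NEITHER
    if rec.violent_or_accidental is None:
        raise CapabilityError(
            "pregnancy-related death lacks the violent/accidental flag; "
            "maternal status undetermined (PRMR only)"
        )
    if rec.violent_or_accidental:
        return DeathClass.PREGNANCY_RELATED_ONLY
    return DeathClass.MATERNAL_AND_PREGNANCY_RELATED


# ---------------------------------------------------------------------------
# Cluster-level aggregation


@dataclass
class ClusterAggregates:
    """Per-cluster additive totals of every estimator input, shape (k, 7).

    Summing rows over any subset of clusters reproduces the estimator's
    inputs on that subsample, which is what makes delete-one-cluster
    replication cheap.
    """

    cluster_keys: pd.DataFrame          # columns: stratum, cluster
    n_resp: np.ndarray                  # weighted respondents by age group at interview
    e_r: np.ndarray                     # respondent exposure years (fertility window)
    b: np.ndarray                       # respondents' live births (fertility window)
    md: np.ndarray                      # maternal deaths (mortality window)
    prd: np.ndarray                     # pregnancy-related deaths (mortality window)
    e_s: np.ndarray                     # sister exposure years (mortality window)
    lb: np.ndarray                      # calendar live births (calendar window)
    sb: np.ndarray                      # calendar stillbirths
    ma: np.ndarray                      # calendar miscarriages/abortions
    config: EstimateConfig
    has_violence_flags: bool

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_keys)

    _FIELDS = ("n_resp", "e_r", "b", "md", "prd", "e_s", "lb", "sb", "ma")

    def totals(self, drop: int | None = None) -> dict[str, np.ndarray]:
        """Column sums over all clusters, optionally deleting one."""
        full = getattr(self, "_full_totals", None)
        if full is None:
            full = {name: getattr(self, name).sum(axis=0) for name in self._FIELDS}
            object.__setattr__(self, "_full_totals", full)
        if drop is None:
            return {name: tot.copy() for name, tot in full.items()}
        return {name: full[name] - getattr(self, name)[drop] for name in self._FIELDS}


def aggregate(survey: Survey, config: EstimateConfig | None = None) -> ClusterAggregates:
    """One pass over the survey producing per-cluster estimator inputs."""
    config = config or EstimateConfig()
    resp = survey.respondents
    key = resp["stratum"].astype(str) + "\x1f" + resp["cluster"].astype(str)
    codes, uniques = pd.factorize(key)
    k = len(uniques)
    keys = pd.DataFrame(
        [u.split("\x1f", 1) for u in uniques], columns=["stratum", "cluster"]
    )

    weight = resp["weight"].to_numpy(dtype=float)
    dob = resp["dob_cmc"].to_numpy(dtype=np.int64)
    interview = resp["interview_cmc"].to_numpy(dtype=np.int64)

    def zeros() -> np.ndarray:
        return np.zeros((k, N_AGE_GROUPS), dtype=float)

    # --- respondents: age composition and fertility exposure
    n_resp = zeros()
    rgroup = age_group_index_from_months(interview - dob)
    ok = rgroup >= 0
    np.add.at(n_resp, (codes[ok], rgroup[ok]), weight[ok])

    f_start, f_end = config.window_bounds(interview, config.fertility_years)
    e_r = zeros()
    months = person_months_between(dob, np.nan, f_start, f_end)
    np.add.at(e_r, codes, weight[:, None] * (months / 12.0))

    # --- respondents' live births in the fertility window
    b = zeros()
    preg = survey.pregnancies
    pos = pd.Index(resp["resp_id"])
    if len(preg):
        p_at = pos.get_indexer(preg["resp_id"])
        end = preg["end_cmc"].to_numpy(dtype=np.int64)
        live = (preg["outcome"] == PregnancyOutcome.LIVE_BIRTH.value).to_numpy()
        in_win = (end >= f_start[p_at]) & (end <= f_end[p_at])
        g = age_group_index_from_months(end - dob[p_at])
        keep = live & in_win & (g >= 0)
        np.add.at(b, (codes[p_at[keep]], g[keep]), weight[p_at[keep]])

    # --- calendar outcome distribution (5-year window)
    lb, sb, ma = zeros(), zeros(), zeros()
    if len(preg):
        c_start, c_end = config.window_bounds(interview, config.calendar_years)
        in_cal = (end >= c_start[p_at]) & (end <= c_end[p_at])
        keep = in_cal & (g >= 0)
        cls = classify_outcomes_frame(preg).to_numpy()
        for table, oc in ((lb, OutcomeClass.LIVE_BIRTH), (sb, OutcomeClass.STILLBIRTH),
                          (ma, OutcomeClass.MISCARRIAGE_OR_ABORTION)):
            m = keep & (cls == oc.value)
            np.add.at(table, (codes[p_at[m]], g[m]), weight[p_at[m]])

    # --- sisters: exposure and deaths in the mortality window
    md, prd, e_s = zeros(), zeros(), zeros()
    sib = survey.siblings
    if len(sib):
        female = (sib["sex"] == Sex.FEMALE.value).to_numpy()
        s_at = pos.get_indexer(sib["resp_id"])[female]
        s_codes = codes[s_at]
        s_w = weight[s_at]
        s_dob = sib["dob_cmc"].to_numpy(dtype=np.int64)[female]
        s_dod = sib["dod_cmc"].to_numpy(dtype=float)[female]
        m_start, m_end = config.window_bounds(interview[s_at], config.mortality_years)

        s_months = person_months_between(s_dob, s_dod, m_start, m_end)
        np.add.at(e_s, s_codes, s_w[:, None] * (s_months / 12.0))

        dead = ~np.isnan(s_dod)
        timing = sib["death_timing"].astype(str).to_numpy()[female]
        pr = dead & np.isin(timing, list(PREGNANCY_RELATED_TIMINGS))
        dod_i = np.where(dead, s_dod, 0).astype(np.int64)
        in_win = (dod_i >= m_start) & (dod_i <= m_end)
        g_d = age_group_index_from_months(dod_i - s_dob)
        prd_mask = pr & in_win & (g_d >= 0)
        np.add.at(prd, (s_codes[prd_mask], g_d[prd_mask]), s_w[prd_mask])

        violent = sib["violent"].to_numpy(dtype=object)[female]
        nonviolent = np.array([v is False or v == 0 for v in violent], dtype=bool)
        md_mask = prd_mask & nonviolent
        np.add.at(md, (s_codes[md_mask], g_d[md_mask]), s_w[md_mask])

    return ClusterAggregates(
        cluster_keys=keys,
        n_resp=n_resp, e_r=e_r, b=b, md=md, prd=prd, e_s=e_s,
        lb=lb, sb=sb, ma=ma,
        config=config,
        has_violence_flags=survey.has_violence_flags,
    )


def _point_from_totals(
    t: dict[str, np.ndarray],
    metric: Metric,
    scenario: Scenario,
    calendar_window: Window,
) -> float:
    """Assemble the mortality ratio from summed estimator inputs."""
    n = t["n_resp"]
    if n.sum() <= 0:
        raise DegenerateInputError("no respondents")
    c = n / n.sum()

    dist = OutcomeDistribution(
        AgeGroupTable(t["lb"]), AgeGroupTable(t["sb"]), AgeGroupTable(t["ma"]),
        calendar_window,
    )
    a = adjustment_factors(dist, scenario, required_groups=t["b"] > 0, warn_empty=False)

    b, e_r = t["b"], t["e_r"]
    if np.any((b > 0) & (e_r <= 0)):
        raise DegenerateInputError("live births in a group with zero respondent exposure")
    fert_rate = np.where(e_r > 0, b / np.where(e_r > 0, e_r, 1.0), 0.0)
    gfr_value = float(np.sum(fert_rate * c * a.values))
    if gfr_value <= 0:
        raise DegenerateInputError("general fertility rate is zero")

    d = t["md"] if metric is Metric.MMR else t["prd"]
    e_s = t["e_s"]
    if np.any((d > 0) & (e_s <= 0)):
        raise DegenerateInputError("deaths in a group with zero sister exposure")
    mort_rate = np.where(e_s > 0, d / np.where(e_s > 0, e_s, 1.0), 0.0)
    return float(np.sum(mort_rate * c) / gfr_value * PER)


def estimate_from_aggregates(
    agg: ClusterAggregates,
    metric,
    scenario,
    variance: bool = True,
) -> RatioEstimate:
    """Point estimate (and jackknife SE/CI) from precomputed cluster totals."""
    metric = Metric.coerce(metric)
    scenario = Scenario(scenario)
    if metric is Metric.MMR and not agg.has_violence_flags:
        raise CapabilityError(
            "survey lacks violent/accidental death flags; MMR unavailable (PRMR only)"
        )
    cal = Window(0, agg.config.calendar_years * 12 - 1, label="calendar")
    point = _point_from_totals(agg.totals(), metric, scenario, cal)
    est = RatioEstimate(metric=metric.value, scenario=scenario, value=point)
    k = agg.n_clusters
    if variance and k >= 2:
        replicates, failures = [], []
        for i in range(k):
            try:
                replicates.append(_point_from_totals(agg.totals(drop=i), metric, scenario, cal))
            except DegenerateInputError:
                failures.append(i)
        if failures and not agg.config.drop_failing_replicates:
            from .errors import ReplicateFailureError

            bad = agg.cluster_keys.iloc[failures]
            raise ReplicateFailureError(
                f"ratio undefined on {len(failures)} delete-one-cluster subsample(s): "
                f"{list(bad.itertuples(index=False, name=None))[:10]}"
            )
        jk = jackknife_from_replicates(point, replicates, z=Z_95, n_dropped=len(failures))
        est.se, est.ci_low, est.ci_high = jk.se, jk.ci_low, jk.ci_high
        est.n_clusters = k
        est.n_dropped_replicates = jk.n_dropped_replicates
        est.replicate_values = jk.replicate_values
    return est


def estimate(
    survey: Survey,
    metric,
    scenario,
    config: EstimateConfig | None = None,
    variance: bool = True,
) -> RatioEstimate:
    """Full pipeline: validate, aggregate, assemble the ratio, jackknife it.

    ``scenario='live_births'`` reproduces the conventional indicator; the
    alternative scenarios change only the adjustment factors A_x inside the
    GFR, never the numerator.
    """
    require_valid(survey)
    agg = aggregate(survey, config)
    return estimate_from_aggregates(agg, metric, scenario, variance=variance)


# ---------------------------------------------------------------------------
# Spec-level building blocks (thin views over the same aggregation pass)


def mortality_inputs(
    survey: Survey, years: int = 7, config: EstimateConfig | None = None
) -> MortalityInputs:
    """Weighted death counts, sister exposure years, and respondent composition C_x."""
    config = config or EstimateConfig(mortality_years=years)
    if config.mortality_years != years:
        config = EstimateConfig(**{**config.to_dict(), "mortality_years": years})
    agg = aggregate(survey, config)
    t = agg.totals()
    if t["e_s"].sum() <= 0:
        raise DegenerateInputError("zero sister exposure everywhere")
    c = t["n_resp"] / t["n_resp"].sum()
    md = AgeGroupTable(t["md"]) if agg.has_violence_flags else None
    return MortalityInputs(
        md=md,
        prd=AgeGroupTable(t["prd"]),
        e_s=AgeGroupTable(t["e_s"]),
        c=AgeGroupTable(c),
        window_years=years,
    )


def fertility_inputs(
    survey: Survey,
    scenario=Scenario.LIVE_BIRTHS,
    years: int = 7,
    config: EstimateConfig | None = None,
) -> FertilityInputs:
    """Respondents' live births, exposure years, and adjustment factors A_x."""
    config = config or EstimateConfig(fertility_years=years)
    if config.fertility_years != years:
        config = EstimateConfig(**{**config.to_dict(), "fertility_years": years})
    agg = aggregate(survey, config)
    t = agg.totals()
    cal = Window(0, config.calendar_years * 12 - 1, label="calendar")
    dist = OutcomeDistribution(
        AgeGroupTable(t["lb"]), AgeGroupTable(t["sb"]), AgeGroupTable(t["ma"]), cal
    )
    a = adjustment_factors(dist, scenario, required_groups=t["b"] > 0, warn_empty=False)
    return FertilityInputs(
        b=AgeGroupTable(t["b"]), e_r=AgeGroupTable(t["e_r"]), a=a, window_years=years
    )


def gfr(f: FertilityInputs, c: AgeGroupTable) -> float:
    """Age-standardised general fertility rate: sum_x (B_x/E_Rx) C_x A_x.

    Births per woman-year; with all A_x = 1 this is the unadjusted GFR.
    """
    b, e_r = f.b.values, f.e_r.values
    if np.any((b > 0) & (e_r <= 0)):
        raise DegenerateInputError("live births in a group with zero exposure")
    rate = np.where(e_r > 0, b / np.where(e_r > 0, e_r, 1.0), 0.0)
    return float(np.sum(rate * c.values * f.a.values))


def mortality_ratio(m: MortalityInputs, gfr_value: float, metric) -> float:
    """Point ratio per 100,000: [sum_x (D_x/E_Sx) C_x] / GFR * 100,000."""
    metric = Metric.coerce(metric)
    if gfr_value <= 0:
        raise DegenerateInputError("general fertility rate must be positive")
    if metric is Metric.MMR:
        if m.md is None:
            raise CapabilityError("maternal deaths unavailable (no violence flags)")
        d = m.md.values
    else:
        d = m.prd.values
    e_s = m.e_s.values
    if np.any((d > 0) & (e_s <= 0)):
        raise DegenerateInputError("deaths in a group with zero sister exposure")
    rate = np.where(e_s > 0, d / np.where(e_s > 0, e_s, 1.0), 0.0)
    return float(np.sum(rate * m.c.values) / gfr_value * PER)
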