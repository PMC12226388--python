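"""Synthetic DHS-like surveys with known ground truth.

Real sibling-survival microdata are access-restricted, so the pipeline is
exercised and validated on simulated surveys whose true rates are set by
:class:`SimulationParams`. The generator draws a stratified cluster sample
of women 15-49 with sampling weights; each woman's sibling roster with
monthly survival where a configurable share of adult female deaths are
pregnancy-related (and a sub-share of those violent/accidental); and each
woman's pregnancy record with age-specific live-birth rates and a stated
live-birth / stillbirth / miscarriage-abortion outcome mix. All event dates
are century-month codes.

Because every rate is known, the ratio the estimator should recover has a
closed form (:func:`expected_ratio`), enabling parameter-recovery tests of
the entire pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adjustment import Scenario
from .data_model import DeathTiming, PregnancyOutcome, Sex, Survey
from .demographic_time import cmc
from .errors import ParameterError
from .estimation import Metric, PER
from .agegroups import AGE_GROUP_LABELS, MIN_AGE_MONTHS, N_AGE_GROUPS, age_group_index_from_months

__all__ = ["SimulationParams", "generate_survey", "expected_ratio"]

#: Reported timing split among pregnancy-related deaths
#: (during pregnancy / during delivery / within two months postpartum).
TIMING_SPLIT = (0.35, 0.25, 0.40)
_PR_TIMINGS = (
    DeathTiming.DURING_PREGNANCY.value,
    DeathTiming.DURING_DELIVERY.value,
    DeathTiming.WITHIN_TWO_MONTHS_POSTPARTUM.value,
)


@dataclass
class SimulationParams:
    """Ground-truth rates and design parameters for one synthetic survey.

    Defaults describe a high-fertility, high-mortality setting of the kind
    the sisterhood method is used in: age-standardised GFR ~0.13 births per
    woman-year, ~88.5% of pregnancies ending in live birth, and a
    pregnancy-related mortality ratio around 550 per 100,000 live births.

    Rates are annual; ``f_x`` is the live-birth rate per woman-year by the
    mother's five-year age group, ``prm_x`` the pregnancy-related death rate
    per woman-year among women, and ``outcome_mix`` the per-group
    (live birth, stillbirth, miscarriage/abortion) probabilities, each
    triple summing to 1.
    """

    n_strata: int = 5
    clusters_per_stratum: int = 10
    respondents_per_cluster: int = 25
    weight_model: str = "lognormal"          # "equal" or "lognormal"
    weight_sigma: float = 0.25
    age_distribution: tuple = (0.22, 0.19, 0.17, 0.14, 0.12, 0.09, 0.07)
    mean_sisters: float = 2.5
    mean_brothers: float = 2.5
    sister_age_spread_months: int = 120
    f_x: tuple = (0.10, 0.20, 0.19, 0.15, 0.10, 0.05, 0.01)
    outcome_mix: tuple = ((0.885, 0.015, 0.10),) * N_AGE_GROUPS
    prm_x: tuple = (0.0004, 0.0005, 0.0006, 0.0008, 0.0010, 0.0012, 0.0014)
    violent_share: float = 0.12
    background_mortality: float = 0.003
    background_violent_share: float = 0.20
    record_years: int = 7
    interview_year: int = 2022
    interview_month: int = 7
    #: Optional reporting biases, off by default: probability that a sibling
    #: is omitted from the roster, and that a non-live pregnancy outcome
    #: goes unreported.
    sibling_omission_prob: float = 0.0
    loss_underreport_prob: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    @property
    def n_respondents(self) -> int:
        return self.n_strata * self.clusters_per_stratum * self.respondents_per_cluster

    @property
    def interview_cmc(self) -> int:
        return cmc(self.interview_year, self.interview_month)

    def mix_array(self) -> np.ndarray:
        """(7, 3) array of per-group (p_LB, p_SB, p_MA)."""
        mix = np.asarray(self.outcome_mix, dtype=float)
        if mix.shape == (3,):
            mix = np.tile(mix, (N_AGE_GROUPS, 1))
        if mix.shape != (N_AGE_GROUPS, 3):
            raise ParameterError(f"outcome_mix must be 7 triples, got shape {mix.shape}")
        return mix

    def validate(self) -> None:
        age = np.asarray(self.age_distribution, dtype=float)
        if age.shape != (N_AGE_GROUPS,) or np.any(age < 0) or not np.isclose(age.sum(), 1.0):
            raise ParameterError("age_distribution must be 7 non-negative shares summing to 1")
        mix = self.mix_array()
        if np.any(mix < 0) or np.any(mix > 1) or not np.allclose(mix.sum(axis=1), 1.0):
            raise ParameterError("each outcome_mix triple must be probabilities summing to 1")
        f = np.asarray(self.f_x, dtype=float)
        prm = np.asarray(self.prm_x, dtype=float)
        if f.shape != (N_AGE_GROUPS,) or np.any(f < 0):
            raise ParameterError("f_x must be 7 non-negative rates")
        if prm.shape != (N_AGE_GROUPS,) or np.any(prm < 0):
            raise ParameterError("prm_x must be 7 non-negative rates")
        if not 0 <= self.violent_share <= 1:
            raise ParameterError("violent_share must be a probability")
        if self.background_mortality < 0:
            raise ParameterError("background_mortality must be non-negative")
        p_lb = mix[:, 0]
        if np.any((f > 0) & (p_lb <= 0)):
            raise ParameterError("f_x > 0 requires p_LB > 0 in that group")
        with np.errstate(divide="ignore", invalid="ignore"):
            hazard = np.where(p_lb > 0, f / (12.0 * np.where(p_lb > 0, p_lb, 1.0)), 0.0)
        if np.any(hazard >= 1):
            raise ParameterError("monthly pregnancy hazard f_x/(12 p_LB) reaches 1: infeasible")
        if np.any((self.background_mortality + prm) / 12.0 >= 1):
            raise ParameterError("monthly death hazard reaches 1: infeasible")
        if self.weight_model not in ("equal", "lognormal"):
            raise ParameterError(f"unknown weight_model {self.weight_model!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("age_distribution", "f_x", "prm_x"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "outcome_mix" in raw:
            raw["outcome_mix"] = tuple(tuple(t) for t in np.atleast_2d(raw["outcome_mix"]))
        p = cls(**raw)
        p.validate()
        return p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcome_mix"] = [[float(x) for x in t] for t in self.mix_array()]
        for key in ("age_distribution", "f_x", "prm_x"):
            d[key] = [float(x) for x in d[key]]
        return d


def _death_month(rng, hazard: np.ndarray) -> np.ndarray:
    """First month (index) where a monthly death draw fires, else -1.

    ``hazard`` is (N, M) per-month death probability.
    """
    u = rng.random(hazard.shape)
    hit = u < hazard
    any_hit = hit.any(axis=1)
    first = hit.argmax(axis=1)
    return np.where(any_hit, first, -1)


def generate_survey(params: SimulationParams, seed: int | None = None) -> Survey:
    """Draw one synthetic survey; a fixed seed gives byte-identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_respondents
    iv = params.interview_cmc
    window_months = 12 * params.record_years
    win_start = iv - window_months          # window is [win_start, iv-1]
    months = win_start + np.arange(window_months)

    # --- design: strata, clusters, weights
    stratum = np.repeat(
        [f"S{i + 1}" for i in range(params.n_strata)],
        params.clusters_per_stratum * params.respondents_per_cluster,
    )
    cluster = np.repeat(
        [
            f"S{i + 1}C{j + 1}"
            for i in range(params.n_strata)
            for j in range(params.clusters_per_stratum)
        ],
        params.respondents_per_cluster,
    )
    if params.weight_model == "equal":
        weight = np.ones(n)
    else:
        sig = params.weight_sigma
        weight = rng.lognormal(mean=-0.5 * sig * sig, sigma=sig, size=n)

    # --- respondent ages
    age_group = rng.choice(N_AGE_GROUPS, size=n, p=np.asarray(params.age_distribution))
    age_months = MIN_AGE_MONTHS + 60 * age_group + rng.integers(0, 60, size=n)
    dob = iv - age_months
    resp_id = np.array([f"R{i + 1:06d}" for i in range(n)])

    respondents = pd.DataFrame(
        {
            "resp_id": resp_id,
            "weight": weight,
            "cluster": cluster,
            "stratum": stratum,
            "dob_cmc": dob,
            "interview_cmc": np.full(n, iv),
        }
    )

    # --- siblings: monthly survival over the record window, all alive at its start
    prm = np.asarray(params.prm_x, dtype=float)
    sib_frames = []
    for sex, mean_count in ((Sex.FEMALE, params.mean_sisters), (Sex.MALE, params.mean_brothers)):
        count = rng.poisson(mean_count, size=n)
        total = int(count.sum())
        if total == 0:
            continue
        owner = np.repeat(np.arange(n), count)
        offset = rng.integers(
            -params.sister_age_spread_months, params.sister_age_spread_months + 1, size=total
        )
        s_dob = dob[owner] + offset

        age_by_month = months[None, :] - s_dob[:, None]
        g = age_group_index_from_months(age_by_month)
        pr_rate = np.where(g >= 0, prm[np.clip(g, 0, N_AGE_GROUPS - 1)], 0.0)
        if sex is Sex.MALE:
            pr_rate = np.zeros_like(pr_rate)
        born = age_by_month >= 0
        hazard = np.where(born, (params.background_mortality + pr_rate) / 12.0, 0.0)
        dmonth = _death_month(rng, hazard)

        dead = dmonth >= 0
        dod = np.where(dead, win_start + dmonth, np.nan)
        timing = np.full(total, DeathTiming.NOT_APPLICABLE.value, dtype=object)
        violent = np.full(total, None, dtype=object)

        if sex is Sex.FEMALE:
            g_at_death = np.full(total, -1)
            g_at_death[dead] = age_group_index_from_months(
                dod[dead].astype(np.int64) - s_dob[dead]
            )
            pr_at_death = np.where(g_at_death >= 0, prm[np.clip(g_at_death, 0, 6)], 0.0)
            tot_at_death = params.background_mortality + pr_at_death
            p_pr = np.where(dead & (tot_at_death > 0), pr_at_death / np.where(tot_at_death > 0, tot_at_death, 1.0), 0.0)
            is_pr = rng.random(total) < p_pr
            is_pr &= dead
            timing[dead] = DeathTiming.NONE_OF_THESE.value
            timing[is_pr] = rng.choice(_PR_TIMINGS, size=int(is_pr.sum()), p=TIMING_SPLIT)
            vdraw = rng.random(total)
            violent[dead] = vdraw[dead] < params.background_violent_share
            violent[is_pr] = vdraw[is_pr] < params.violent_share
        else:
            vdraw = rng.random(total)
            violent[dead] = vdraw[dead] < params.background_violent_share

        sib_frames.append(
            pd.DataFrame(
                {
                    "resp_id": resp_id[owner],
                    "sex": sex.value,
                    "alive": ~dead,
                    "dob_cmc": s_dob,
                    "dod_cmc": dod,
                    "death_timing": timing,
                    "violent": violent,
                }
            )
        )
    siblings = pd.concat(sib_frames, ignore_index=True) if sib_frames else pd.DataFrame(
        columns=["resp_id", "sex", "alive", "dob_cmc", "dod_cmc", "death_timing", "violent"]
    )
    if params.sibling_omission_prob > 0 and len(siblings):
        keep = rng.random(len(siblings)) >= params.sibling_omission_prob
        siblings = siblings.loc[keep].reset_index(drop=True)

    # --- pregnancy record: monthly conception-end hazard f_x / (12 p_LB)
    mix = params.mix_array()
    f = np.asarray(params.f_x, dtype=float)
    p_lb = mix[:, 0]
    age_by_month = months[None, :] - dob[:, None]
    g = age_group_index_from_months(age_by_month)
    gc = np.clip(g, 0, N_AGE_GROUPS - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hz_by_group = np.where(p_lb > 0, f / (12.0 * np.where(p_lb > 0, p_lb, 1.0)), 0.0)
    hazard = np.where(g >= 0, hz_by_group[gc], 0.0)
    event = rng.random((n, window_months)) < hazard
    widx, midx = np.nonzero(event)
    n_ev = widx.size

    end_cmc = months[midx]
    g_ev = g[widx, midx]
    u = rng.random(n_ev)
    cum = np.cumsum(mix[g_ev], axis=1)
    oclass = (u[:, None] >= cum).sum(axis=1)  # 0=LB, 1=SB, 2=MA
    duration = np.full(n_ev, 9, dtype=np.int64)
    sb = oclass == 1
    ma = oclass == 2
    duration[sb] = rng.integers(7, 10, size=int(sb.sum()))
    duration[ma] = rng.integers(1, 7, size=int(ma.sum()))
    outcome = np.full(n_ev, PregnancyOutcome.LIVE_BIRTH.value, dtype=object)
    outcome[sb] = PregnancyOutcome.STILLBIRTH.value
    outcome[ma] = PregnancyOutcome.LOSS_UNCLASSIFIED.value

    pregnancies = pd.DataFrame(
        {
            "resp_id": resp_id[widx],
            "end_cmc": end_cmc,
            "duration_months": duration,
            "outcome": outcome,
        }
    )
    if params.loss_underreport_prob > 0 and len(pregnancies):
        nonlive = pregnancies["outcome"] != PregnancyOutcome.LIVE_BIRTH.value
        drop = nonlive.to_numpy() & (rng.random(len(pregnancies)) < params.loss_underreport_prob)
        pregnancies = pregnancies.loc[~drop].reset_index(drop=True)

    meta = {
        "label": params.label,
        "interview_cmc": int(iv),
        "record_years": int(params.record_years),
        "seed": int(params.seed if seed is None else seed),
        "n_respondents": int(n),
    }
    return Survey(respondents, siblings, pregnancies, meta=meta)


def expected_ratio(params: SimulationParams, metric, scenario) -> float:
    """Closed-form ratio per 100,000 implied by the simulation parameters.

    C_x is the respondent age distribution; the true adjustment factors are
    A_x(total births) = (p_LB + p_SB)/p_LB and A_x(total pregnancies) =
    1/p_LB; GFR = sum f_x C_x A_x; the numerator is sum prm_x C_x, times
    (1 - violent_share) for MMR.
    """
    params.validate()
    metric = Metric.coerce(metric)
    scenario = Scenario(scenario)
    c = np.asarray(params.age_distribution, dtype=float)
    f = np.asarray(params.f_x, dtype=float)
    prm = np.asarray(params.prm_x, dtype=float)
    mix = params.mix_array()
    p_lb, p_sb = mix[:, 0], mix[:, 1]
    if np.any((f > 0) & (p_lb <= 0)):
        raise ParameterError("p_LB = 0 in a group with f_x > 0")

    if scenario is Scenario.LIVE_BIRTHS:
        a = np.ones(N_AGE_GROUPS)
    elif scenario is Scenario.TOTAL_BIRTHS:
        a = np.where(p_lb > 0, (p_lb + p_sb) / np.where(p_lb > 0, p_lb, 1.0), 1.0)
    else:
        a = np.where(p_lb > 0, 1.0 / np.where(p_lb > 0, p_lb, 1.0), 1.0)

    gfr = float(np.sum(f * c * a))
    if gfr <= 0:
        raise ParameterError("expected GFR is zero")
    numer = float(np.sum(prm * c))
    if metric is Metric.MMR:
        numer *= 1.0 - params.violent_share
    return numer / gfr * PER
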