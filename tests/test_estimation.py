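"""Death classification, rate inputs, GFR, and ratio assembly."""

import numpy as np
import pytest

from matdenom import (
    AgeGroupTable,
    DeathClass,
    EstimateConfig,
    FertilityInputs,
    Metric,
    MortalityInputs,
    Scenario,
    Sex,
    SiblingRecord,
    Survey,
    classify_death,
    estimate,
    fertility_inputs,
    gfr,
    mortality_inputs,
    mortality_ratio,
)
from matdenom.data_model import DeathTiming
from matdenom.errors import CapabilityError, DegenerateInputError

from conftest import (
    INTERVIEW,
    make_dead_sister,
    make_live_birth,
    make_respondent,
    month_enumeration_exposure,
)


def dead_sister(timing, violent):
    return SiblingRecord(
        "R1", Sex.FEMALE, False, 1000, dod_cmc=1300, death_timing=timing,
        violent_or_accidental=violent,
    )


class TestClassifyDeath:
    @pytest.mark.parametrize(
        "timing,violent,expected",
        [
            (DeathTiming.DURING_DELIVERY, False, DeathClass.MATERNAL_AND_PREGNANCY_RELATED),
            (DeathTiming.DURING_PREGNANCY, False, DeathClass.MATERNAL_AND_PREGNANCY_RELATED),
            (DeathTiming.WITHIN_TWO_MONTHS_POSTPARTUM, True, DeathClass.PREGNANCY_RELATED_ONLY),
            (DeathTiming.NONE_OF_THESE, False, DeathClass.NEITHER),
            (DeathTiming.NONE_OF_THESE, True, DeathClass.NEITHER),
        ],
    )
    def test_timing_and_violence_rules(self, timing, violent, expected):
        assert classify_death(dead_sister(timing, violent)) is expected

    def test_rejects_living_and_male(self):
        alive = SiblingRecord("R1", Sex.FEMALE, True, 1000)
        with pytest.raises(ValueError):
            classify_death(alive)
        brother = SiblingRecord(
            "R1", Sex.MALE, False, 1000, dod_cmc=1300,
            death_timing=DeathTiming.NOT_APPLICABLE, violent_or_accidental=False,
        )
        with pytest.raises(ValueError):
            classify_death(brother)

    def test_missing_violence_flag_is_a_capability_error(self):
        with pytest.raises(CapabilityError):
            classify_death(dead_sister(DeathTiming.DURING_DELIVERY, None))


class TestMortalityInputs:
    def test_single_sister_death_counts_and_exposure(self):
        resp = make_respondent("R1", age_years=30)
        dob_s = INTERVIEW - 366  # sister slightly older than the 7-year window needs
        dod_s = dob_s + 324      # dies aged exactly 27 years
        sib = make_dead_sister("R1", dob_s, dod_s, DeathTiming.DURING_PREGNANCY, violent=False)
        s = Survey.from_records([resp], [sib])
        m = mortality_inputs(s, years=7)
        assert m.prd["25-29"] == 1.0 and m.prd.sum() == 1.0
        assert m.md["25-29"] == 1.0
        oracle = month_enumeration_exposure(dob_s, dod_s, INTERVIEW - 84, INTERVIEW - 1)
        assert list(m.e_s) == oracle
        assert m.c["30-34"] == 1.0

    def test_weighted_age_composition(self):
        resp = [
            make_respondent("R1", age_years=16, weight=1.0),
            make_respondent("R2", age_years=17, weight=1.0),
            make_respondent("R3", age_years=22, weight=2.0),
        ]
        sib = [make_dead_sister("R1", INTERVIEW - 400, INTERVIEW - 10)]
        m = mortality_inputs(Survey.from_records(resp, sib))
        assert list(m.c) == [0.5, 0.5, 0, 0, 0, 0, 0]
        assert m.c.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_window_or_out_of_age_deaths_excluded(self):
        resp = make_respondent("R1", age_years=30)
        sibs = [
            # dies before the window opens (window starts at INTERVIEW - 84)
            make_dead_sister("R1", INTERVIEW - 500, INTERVIEW - 100,
                             DeathTiming.DURING_DELIVERY),
            # dies in-window but aged 50 (605 completed months)
            make_dead_sister("R1", INTERVIEW - 650, INTERVIEW - 45,
                             DeathTiming.DURING_DELIVERY),
            # dies in-window aged 33: the only counted death
            make_dead_sister("R1", INTERVIEW - 445, INTERVIEW - 45,
                             DeathTiming.DURING_DELIVERY),
        ]
        m = mortality_inputs(Survey.from_records([resp], sibs))
        assert m.prd.sum() == 1.0
        assert m.prd["30-34"] == 1.0

    def test_brute_force_retally_on_simulated_survey(self, tiny_survey):
        m = mortality_inputs(tiny_survey, years=7)
        prd = [0.0] * 7
        md = [0.0] * 7
        e_s = [0.0] * 7
        resp = tiny_survey.respondents.set_index("resp_id")
        pr = {"during_pregnancy", "during_delivery", "within_two_months_postpartum"}
        for _, row in tiny_survey.siblings.iterrows():
            if row["sex"] != "female":
                continue
            mother = resp.loc[row["resp_id"]]
            iv = int(mother["interview_cmc"])
            start, end = iv - 84, iv - 1
            dod = None if np.isnan(row["dod_cmc"]) else int(row["dod_cmc"])
            w = float(mother["weight"])
            for g, yrs in enumerate(month_enumeration_exposure(int(row["dob_cmc"]), dod, start, end)):
                e_s[g] += w * yrs
            if dod is not None and start <= dod <= end and row["death_timing"] in pr:
                age = dod - int(row["dob_cmc"])
                if 180 <= age <= 599:
                    g = (age - 180) // 60
                    prd[g] += w
                    if not row["violent"]:
                        md[g] += w
        assert np.allclose(m.prd.values, prd, rtol=1e-12)
        assert np.allclose(m.md.values, md, rtol=1e-12)
        assert np.allclose(m.e_s.values, e_s, rtol=1e-9)


def single_group_inputs(d=0.8, e_s=1000.0, md_scale=1.0):
    c = AgeGroupTable([1, 0, 0, 0, 0, 0, 0])
    m = MortalityInputs(
        md=AgeGroupTable([d * md_scale, 0, 0, 0, 0, 0, 0]),
        prd=AgeGroupTable([d, 0, 0, 0, 0, 0, 0]),
        e_s=AgeGroupTable([e_s, 0, 0, 0, 0, 0, 0]),
        c=c,
    )
    return m, c


class TestGfrAndRatio:
    def test_gfr_single_group(self):
        c = AgeGroupTable([1, 0, 0, 0, 0, 0, 0])
        f = FertilityInputs(
            b=AgeGroupTable([40, 0, 0, 0, 0, 0, 0]),
            e_r=AgeGroupTable([250, 1, 1, 1, 1, 1, 1]),
            a=AgeGroupTable(1.0),
        )
        assert gfr(f, c) == pytest.approx(0.16)
        f.a = AgeGroupTable(1.125)
        assert gfr(f, c) == pytest.approx(0.18)

    def test_gfr_two_groups_standardised(self):
        c = AgeGroupTable([0.5, 0.5, 0, 0, 0, 0, 0])
        f = FertilityInputs(
            b=AgeGroupTable([10, 40, 0, 0, 0, 0, 0]),
            e_r=AgeGroupTable([100, 200, 1, 1, 1, 1, 1]),
            a=AgeGroupTable(1.0),
        )
        assert gfr(f, c) == pytest.approx(0.15)

    def test_gfr_zero_exposure_with_births(self):
        c = AgeGroupTable([1, 0, 0, 0, 0, 0, 0])
        f = FertilityInputs(
            b=AgeGroupTable([40, 0, 0, 0, 0, 0, 0]),
            e_r=AgeGroupTable(0.0),
            a=AgeGroupTable(1.0),
        )
        with pytest.raises(DegenerateInputError):
            gfr(f, c)

    def test_ratio_worked_example(self):
        m, _ = single_group_inputs()  # rate 0.0008 per woman-year
        assert mortality_ratio(m, 0.16, Metric.PRMR) == pytest.approx(500.0)

    def test_mmr_equals_prmr_when_all_deaths_nonviolent(self):
        m, _ = single_group_inputs(md_scale=1.0)
        assert mortality_ratio(m, 0.16, "mmr") == mortality_ratio(m, 0.16, "prmr")

    def test_uniform_adjustment_factorises(self):
        m, c = single_group_inputs()
        f = FertilityInputs(
            b=AgeGroupTable([40, 0, 0, 0, 0, 0, 0]),
            e_r=AgeGroupTable([250, 1, 1, 1, 1, 1, 1]),
            a=AgeGroupTable(1.0),
        )
        base = mortality_ratio(m, gfr(f, c), "prmr")
        f.a = AgeGroupTable(1.25)
        assert mortality_ratio(m, gfr(f, c), "prmr") == pytest.approx(base / 1.25, rel=1e-12)

    def test_deaths_without_exposure_degenerate(self):
        m, _ = single_group_inputs(e_s=0.0)
        with pytest.raises(DegenerateInputError):
            mortality_ratio(m, 0.16, "prmr")


class TestEstimatePipeline:
    def test_matches_hand_composed_pipeline(self, tiny_survey):
        cfg = EstimateConfig()
        for metric in ("prmr", "mmr"):
            for sc in Scenario:
                est = estimate(tiny_survey, metric, sc, cfg, variance=False)
                m = mortality_inputs(tiny_survey, config=cfg)
                f = fertility_inputs(tiny_survey, scenario=sc, config=cfg)
                by_hand = mortality_ratio(m, gfr(f, m.c), metric)
                assert est.value == pytest.approx(by_hand, rel=1e-12)

    def test_zero_stillbirths_makes_total_births_identical(self):
        params_resp = [make_respondent(f"R{i}", age_years=25 + i, cluster=f"C{i%2}") for i in range(4)]
        sibs = [make_dead_sister("R0", INTERVIEW - 400, INTERVIEW - 20)]
        pregs = [make_live_birth(f"R{i}", INTERVIEW - 30) for i in range(4)]
        s = Survey.from_records(params_resp, sibs, pregs)
        lb = estimate(s, "prmr", Scenario.LIVE_BIRTHS, variance=False)
        tb = estimate(s, "prmr", Scenario.TOTAL_BIRTHS, variance=False)
        assert lb.value == tb.value

    def test_invariant_to_global_weight_rescaling(self, tiny_survey):
        scaled = Survey(
            tiny_survey.respondents.assign(weight=tiny_survey.respondents["weight"] * 7.3),
            tiny_survey.siblings,
            tiny_survey.pregnancies,
        )
        for sc in Scenario:
            a = estimate(tiny_survey, "prmr", sc, variance=False).value
            b = estimate(scaled, "prmr", sc, variance=False).value
            assert a == pytest.approx(b, rel=1e-12)

    def test_invariant_to_record_permutation(self, tiny_survey):
        shuffled = Survey(
            tiny_survey.respondents.sample(frac=1, random_state=1).reset_index(drop=True),
            tiny_survey.siblings.sample(frac=1, random_state=2).reset_index(drop=True),
            tiny_survey.pregnancies.sample(frac=1, random_state=3).reset_index(drop=True),
        )
        a = estimate(tiny_survey, "prmr", Scenario.TOTAL_PREGNANCIES, variance=False).value
        b = estimate(shuffled, "prmr", Scenario.TOTAL_PREGNANCIES, variance=False).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_scenario_ordering_and_metric_ordering(self, medium_survey):
        vals = {
            sc: estimate(medium_survey, "prmr", sc, variance=False).value for sc in Scenario
        }
        assert vals[Scenario.LIVE_BIRTHS] >= vals[Scenario.TOTAL_BIRTHS]
        assert vals[Scenario.TOTAL_BIRTHS] >= vals[Scenario.TOTAL_PREGNANCIES]
        prmr = estimate(medium_survey, "prmr", Scenario.LIVE_BIRTHS, variance=False).value
        mmr = estimate(medium_survey, "mmr", Scenario.LIVE_BIRTHS, variance=False).value
        assert prmr >= mmr

    def test_mmr_without_violence_flags_is_a_capability_error(self):
        resp = make_respondent("R1", age_years=29)  # same age group at birth and interview
        sib = SiblingRecord(
            "R1", Sex.FEMALE, False, INTERVIEW - 400, dod_cmc=INTERVIEW - 60,
            death_timing=DeathTiming.DURING_DELIVERY, violent_or_accidental=None,
        )  # sister dies aged 340 months: same group as the respondent's C_x mass
        s = Survey.from_records([resp], [sib], [make_live_birth("R1", INTERVIEW - 30)])
        with pytest.raises(CapabilityError):
            estimate(s, "mmr", Scenario.LIVE_BIRTHS, variance=False)
        # PRMR remains available
        assert estimate(s, "prmr", Scenario.LIVE_BIRTHS, variance=False).value > 0
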