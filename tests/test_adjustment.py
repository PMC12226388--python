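"""Outcome classification, weighted outcome distributions, adjustment factors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matdenom import (
    AgeGroupTable,
    OutcomeClass,
    PregnancyOutcome,
    PregnancyRecord,
    Respondent,
    Scenario,
    Survey,
    Window,
    adjustment_factors,
    classify_outcome,
    outcome_distribution,
)
from matdenom.adjustment import OutcomeDistribution
from matdenom.errors import EmptyDistributionError, UndefinedFactorError

from conftest import INTERVIEW, make_respondent


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "outcome,duration,expected",
        [
            # a loss at seven or more months of gestation is a stillbirth
            (PregnancyOutcome.LOSS_UNCLASSIFIED, 7, OutcomeClass.STILLBIRTH),
            (PregnancyOutcome.STILLBIRTH, 8, OutcomeClass.STILLBIRTH),
            (PregnancyOutcome.MISCARRIAGE, 3, OutcomeClass.MISCARRIAGE_OR_ABORTION),
            (PregnancyOutcome.INDUCED_ABORTION, 2, OutcomeClass.MISCARRIAGE_OR_ABORTION),
            (PregnancyOutcome.LOSS_UNCLASSIFIED, 6, OutcomeClass.MISCARRIAGE_OR_ABORTION),
            (PregnancyOutcome.LIVE_BIRTH, 9, OutcomeClass.LIVE_BIRTH),
        ],
    )
    def test_stillbirth_rule(self, outcome, duration, expected):
        assert classify_outcome(PregnancyRecord("R1", 1000, duration, outcome)) is expected


def one_mother_survey():
    resp = make_respondent("R1", age_years=23.5, weight=2.0)
    preg = [PregnancyRecord("R1", INTERVIEW - 6, 9, PregnancyOutcome.LIVE_BIRTH)]
    return Survey.from_records([resp], pregnancies=preg)


class TestOutcomeDistribution:
    def test_single_weighted_live_birth(self):
        dist = outcome_distribution(one_mother_survey())
        assert dist.lb["20-24"] == 2.0
        assert dist.lb.sum() == 2.0 and dist.sb.sum() == 0 and dist.msc_ab.sum() == 0

    def test_proportions_from_equal_weights(self):
        resp = [make_respondent(f"R{i}", age_years=25) for i in range(100)]
        preg = []
        for i in range(100):
            if i < 70:
                out, dur = PregnancyOutcome.LIVE_BIRTH, 9
            elif i < 82:
                out, dur = PregnancyOutcome.STILLBIRTH, 8
            else:
                out, dur = PregnancyOutcome.MISCARRIAGE, 3
            preg.append(PregnancyRecord(f"R{i}", INTERVIEW - 12, dur, out))
        dist = outcome_distribution(Survey.from_records(resp, pregnancies=preg))
        props = dist.proportions()
        assert props["live_birth"] == pytest.approx(0.70)
        assert props["stillbirth"] == pytest.approx(0.12)
        assert props["miscarriage_or_abortion"] == pytest.approx(0.18)

    def test_out_of_window_and_out_of_age_excluded(self):
        resp = make_respondent("R1", age_years=20)
        preg = [
            PregnancyRecord("R1", INTERVIEW - 61, 9, PregnancyOutcome.LIVE_BIRTH),  # before window
            PregnancyRecord("R1", INTERVIEW - 70, 9, PregnancyOutcome.LIVE_BIRTH),  # mother aged 14
        ]
        with pytest.raises(EmptyDistributionError):
            outcome_distribution(Survey.from_records([resp], pregnancies=preg))

    def test_matches_brute_force_weighted_tally(self, tiny_survey):
        dist = outcome_distribution(tiny_survey, window_years=5)
        # independent per-record re-tally
        tallies = {c: [0.0] * 7 for c in ("lb", "sb", "ma")}
        resp = tiny_survey.respondents.set_index("resp_id")
        for _, p in tiny_survey.pregnancies.iterrows():
            mother = resp.loc[p["resp_id"]]
            iv = int(mother["interview_cmc"])
            if not (iv - 60 <= p["end_cmc"] <= iv - 1):
                continue
            age = int(p["end_cmc"]) - int(mother["dob_cmc"])
            if not 180 <= age <= 599:
                continue
            g = (age - 180) // 60
            if p["outcome"] == "live_birth":
                key = "lb"
            elif int(p["duration_months"]) >= 7:
                key = "sb"
            else:
                key = "ma"
            tallies[key][g] += float(mother["weight"])
        assert np.allclose(dist.lb.values, tallies["lb"], rtol=1e-12)
        assert np.allclose(dist.sb.values, tallies["sb"], rtol=1e-12)
        assert np.allclose(dist.msc_ab.values, tallies["ma"], rtol=1e-12)

    def test_merge_equals_weightwise_addition(self, tiny_survey, medium_survey):
        d1 = outcome_distribution(tiny_survey)
        d2 = outcome_distribution(medium_survey)
        merged = d1 + d2
        assert np.allclose(merged.lb.values, d1.lb.values + d2.lb.values)
        assert merged.total == pytest.approx(d1.total + d2.total)


def dist_from_counts(lb, sb, ma):
    def table(v):
        return AgeGroupTable(np.asarray(v, dtype=float))

    return OutcomeDistribution(table(lb), table(sb), table(ma), Window(1, 60))


class TestAdjustmentFactors:
    def test_worked_arithmetic(self):
        d = dist_from_counts([800] * 7, [20] * 7, [80] * 7)
        tb = adjustment_factors(d, Scenario.TOTAL_BIRTHS)
        tp = adjustment_factors(d, Scenario.TOTAL_PREGNANCIES)
        assert np.all(tb.values == 1.025)
        assert np.all(tp.values == 1.125)

    def test_live_births_scenario_is_neutral(self):
        d = dist_from_counts([800] * 7, [20] * 7, [80] * 7)
        assert np.all(adjustment_factors(d, Scenario.LIVE_BIRTHS).values == 1.0)

    def test_no_stillbirths_means_unit_total_birth_factors(self):
        d = dist_from_counts([500] * 7, [0] * 7, [30] * 7)
        assert np.all(adjustment_factors(d, Scenario.TOTAL_BIRTHS).values == 1.0)

    def test_empty_group_gets_neutral_factor_with_warning(self):
        d = dist_from_counts([100] * 6 + [0], [5] * 6 + [0], [10] * 6 + [0])
        with pytest.warns(UserWarning, match="45-49"):
            a = adjustment_factors(d, Scenario.TOTAL_PREGNANCIES)
        assert a["45-49"] == 1.0

    def test_undefined_factor_names_group(self):
        d = dist_from_counts([100] * 6 + [0], [5] * 7, [10] * 7)
        with pytest.raises(UndefinedFactorError, match="45-49"):
            adjustment_factors(d, Scenario.TOTAL_BIRTHS)
        # not required downstream -> neutral factor instead
        required = np.array([True] * 6 + [False])
        a = adjustment_factors(d, Scenario.TOTAL_BIRTHS, required_groups=required)
        assert a["45-49"] == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        lb=st.lists(st.floats(0.5, 1e4), min_size=7, max_size=7),
        sb=st.lists(st.floats(0, 1e3), min_size=7, max_size=7),
        ma=st.lists(st.floats(0, 1e3), min_size=7, max_size=7),
    )
    def test_ordering_invariant(self, lb, sb, ma):
        d = dist_from_counts(lb, sb, ma)
        tb = adjustment_factors(d, Scenario.TOTAL_BIRTHS).values
        tp = adjustment_factors(d, Scenario.TOTAL_PREGNANCIES).values
        assert np.all(tp >= tb) and np.all(tb >= 1.0)

    def test_scale_invariance_of_factors_and_proportions(self, tiny_survey):
        doubled = Survey(
            tiny_survey.respondents.assign(weight=tiny_survey.respondents["weight"] * 2),
            tiny_survey.siblings,
            tiny_survey.pregnancies,
        )
        d1, d2 = outcome_distribution(tiny_survey), outcome_distribution(doubled)
        for sc in Scenario:
            a1 = adjustment_factors(d1, sc, warn_empty=False)
            a2 = adjustment_factors(d2, sc, warn_empty=False)
            assert a1.allclose(a2)
        p1, p2 = d1.proportions(), d2.proportions()
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], rel=1e-12)
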