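# Methods

## Estimand and estimator

The package estimates the maternal mortality ratio (MMR) and
pregnancy-related mortality ratio (PRMR) from sibling survival histories —
the sisterhood method as implemented in household-survey programmes — and
re-expresses them per 100,000 total births or total pregnancies instead of
live births.

A sister's death is **pregnancy-related** when the respondent reports it as
occurring during pregnancy, during delivery, or within two months of the
end of the pregnancy, irrespective of cause. It is additionally **maternal**
when not attributed to violence or an accident. This survey definition of
maternal death is wider than ICD-11 (incidental non-violent causes are not
excluded). Surveys whose sibling module lacks the violence/accident flag
support the PRMR only; asking for the MMR raises a capability error rather
than silently treating the flag as absent.

Within five-year age groups x = 15–19 … 45–49:

- age-specific pregnancy-related (and maternal) mortality rates are
  weighted death counts divided by the sisters' weighted person-years of
  exposure over a seven-year window before each interview;
- the rates are composited with the weighted respondent age distribution
  C_x and divided by the general fertility rate for the same window,
  GFR = Σ_x (B_x/E_Rx)·C_x·A_x, built from respondents' own live births
  B_x and exposure E_Rx;
- the denominator scenario enters only through A_x: A_x = 1 (live births),
  (LB_x+SB_x)/LB_x (total births), or (LB_x+SB_x+MSC/AB_x)/LB_x (total
  pregnancies), computed per age group from the weighted outcome
  distribution of pregnancies reported in the five-year calendar window.
  A_x is a per-group ratio, not summed over groups, since it enters the
  GFR inside the sum over x.

Because the three scenarios share every numerator input, the ordering
live_births ≥ total_births ≥ total_pregnancies holds for every survey, and
with an age-constant factor A the adjusted estimate is exactly the
unadjusted one divided by A.

Pregnancy outcomes are classified from gestation duration in completed
months: live births map to themselves; any non-live outcome at ≥ 7 months
is a stillbirth; anything below 7 months (miscarriage, induced abortion, or
an undifferentiated calendar loss) pools into miscarriage-or-abortion. The
instruments record no gestational age in weeks, so this 7-month cut is the
operational stillbirth definition; a recorded duration of exactly 6 months
falls on the miscarriage side, which keeps the "seven or more months" rule
exact. Calendar-style data should not contain unclassified losses at ≥ 7
months; validation flags them as warnings and classification still treats
them as stillbirths.

## Time and exposure conventions

All dates are century-month codes (CMC = 12·(year−1900) + month); readers
also accept year+month column pairs. Reference windows of y years end the
month *before* the interview month (the interview month is only partially
observed), spanning exactly 12y months; a config switch
(`include_interview_month`) exposes the inclusive variant since the
original convention is not documented. The death month counts as exposed.
Exposure is attributed month by month at 1/12 year; months at completed
ages outside 15–49 contribute nothing anywhere (rates, births, outcomes,
deaths). Exposure is computed by exact integer interval overlap per age
group and equals month-by-month enumeration identically, not just to
rounding.

Window defaults: 7 years for mortality and fertility, 5 years for the
calendar outcome distribution that feeds A_x. The 7-vs-5 mismatch is
deliberate: the outcome mix is only observed reliably over the calendar
period, while mortality needs the longer window for death counts; the
factors are treated as stable over the difference.

## Variance

Standard errors come from a delete-one-cluster jackknife: with k clusters
(deleted one at a time within their stratum, all other strata intact),
pseudo-values r_i* = k·r − (k−1)·r_(i) give
SE = sqrt(Σ(r_i* − r̄*)²/(k(k−1))), and 95% CIs use z = 1.96. The exact
stratified-jackknife variant is a documented choice (`variance` module);
negative lower CI bounds are stored untruncated and clipped at zero only
for display. Internally every estimator input is aggregated per cluster
first (additive (k,7) arrays), so each replicate is an array subtraction
rather than a pipeline re-run; a generic subsample-rebuilding jackknife is
also provided and the two agree to numerical precision. Replicates on
which the ratio is undefined (e.g. a deleted cluster held all exposure)
raise by default; `drop_failing_replicates` drops and counts them.

## Synthetic surveys

The generator emulates the features of the data the estimator actually
uses: a stratified cluster sample (default 5 strata × 10 clusters × 25
women) of respondents aged 15–49 with lognormal sampling weights (σ = 0.25,
mean 1); per-respondent sibling rosters (sisters and brothers each
Poisson with mean 2.5, birth dates within ±10 years of the respondent);
and a pregnancy record over the last 7 years with monthly event hazard
f_x/(12·p_LB), outcomes drawn from the per-group mix, and durations that
make outcome classification exactly invertible (live birth 9 months,
stillbirth uniform {7,8,9}, miscarriage/abortion uniform {1..6}).

Default conditions describe a high-burden setting: respondent age shares
(0.22, 0.19, 0.17, 0.14, 0.12, 0.09, 0.07); live-birth rates f_x =
(0.10, 0.20, 0.19, 0.15, 0.10, 0.05, 0.01) per woman-year (age-standardised
GFR ≈ 0.13); outcome mix (88.5% live birth, 1.5% stillbirth, 10%
miscarriage/abortion), within the cross-country ranges reported for
survey calendars; pregnancy-related death rates rising from 4×10⁻⁴ to
14×10⁻⁴ per woman-year with age (PRMR ≈ 554 per 100,000 live births);
12% of pregnancy-related deaths flagged violent/accidental; background
female mortality 0.003/year at all ages.

Simplifications, and hence what passing tests do not show about real data:
sibling deaths are simulated only within the record window (everyone alive
at its start); sisters carry no fertility of their own — death-timing flags
are drawn directly with probability prm_x/(background + prm_x) at the age
of death; monthly pregnancy events are independent (no gestation-length
exclusion between consecutive events, a < 1% effect at these rates); and
reporting is complete by default (sibling omission and loss underreporting
exist as optional probabilities but are off). Real-data biases —
underreported siblings, abortion underreporting, heaped dates, imputed
sibling death dates — are deliberately absent, so validation demonstrates
correctness of the estimator, not robustness to misreporting.

The record window covers the full 7-year fertility window (a pregnancy
history rather than a strict 5-year calendar) so that B_x/E_Rx is
estimable over the same period as mortality; the outcome distribution for
A_x still uses only the last 5 years.

Because every rate is known, expected ratios have closed form: C_x from
the age distribution, true A_x(total births) = (p_LB+p_SB)/p_LB and
A_x(total pregnancies) = 1/p_LB, GFR = Σ f_x·C_x·A_x, numerator
Σ prm_x·C_x (times 1−violent_share for the MMR). Validation shows, over
200 surveys of 5,000 respondents, mean pipeline estimates within 5% of
these values for every metric × scenario and jackknife 95% CI coverage
between 90% and 98%. One survey is generated from a single seeded numpy
Generator in a fixed draw order, so a fixed seed yields byte-identical
output.

## Numerical and design choices

- Weighted tallies use exact float accumulation over records; all
  estimates are invariant to global weight rescaling and record order
  (tested at 10⁻¹² and 10⁻⁹ relative, respectively).
- Age groups with no in-window pregnancies get the neutral factor A_x = 1
  with a warning (they contribute nothing to the fertility numerator);
  a group with zero live births but non-live outcomes has an undefined
  factor and raises when the GFR needs it.
- Malformed input rows are quarantined with their record ids and reported,
  never silently dropped; estimation refuses to run while error-severity
  issues exist. Orphan sibling/pregnancy rows abort the read.
- Sibling death dates must be supplied as CMCs; imputation from "age at
  death + years ago" is not performed, so adapters for raw survey exports
  must resolve imputation upstream. The DHS individual-recode preset is a
  column-name mapping only.
- Respondents do not appear in their own sibling rosters and no
  sibship-size reweighting is applied, matching the standard survey
  implementation of the estimator.
- The estimation windows, interview-month convention, and
  replicate-failure policy are all recorded in `EstimateConfig` and echoed
  into every CLI run's sidecar metadata.

## Problem sizes

The test suite and the acceptance script size their simulations for
desk-scale runs: parameter recovery uses 200 replicates × 5,000
respondents (100 clusters, so each jackknife evaluates 101 cluster
subsets), and the acceptance script reports one 5,000-respondent survey
plus a 60-replicate recovery check. These sizes give Monte-Carlo error an
order of magnitude below the tolerances they are checked against.

## Known limitations

- PRMR/MMR from sibling histories inherit the method's real-world biases
  (survivor bias, omission, recall); the package estimates the survey
  quantity, not a bias-corrected one.
- Only women 15–49 are indexed; deaths and births at other ages are
  excluded by construction.
- Multiple gestations with discordant outcomes cannot be represented: one
  pregnancy record carries one outcome, mirroring the single-entry
  calendar format.
- Ever-married-only samples would need reweighting that is out of scope.
- The normal-approximation CI can cross zero for small death counts; the
  stored bounds are untruncated.
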