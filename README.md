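# matdenom

Sisterhood-method estimation of maternal and pregnancy-related mortality
ratios from DHS-style survey data, with support for **total-birth** and
**total-pregnancy** denominators.

## The problem

The maternal mortality ratio (MMR) and pregnancy-related mortality ratio
(PRMR) are conventionally expressed per 100,000 *live births*, even though
the deaths in their numerators can follow any pregnancy outcome — live
birth, stillbirth, miscarriage, or induced abortion. Where a substantial
share of pregnancies do not end in a live birth, the live-birth denominator
overstates mortality per pregnancy, and the size of that bias varies across
settings with the pregnancy-outcome mix. This package is for demographers
and epidemiologists who want to estimate these ratios from sibling survival
histories and quantify how the choice of denominator changes them.

## The estimator

From each respondent's sibling roster, deaths of sisters during pregnancy,
delivery, or within two months of the end of a pregnancy are
*pregnancy-related*; excluding violent/accidental causes makes them
*maternal* (the household-survey definition, wider than ICD-11). Over a
seven-year window before each interview, with five-year age groups
x = 15–19, …, 45–49 and sampling weights throughout:

    MMR  = Σ_x (MD_x / E_Sx) · C_x / GFR · 100,000
    PRMR = Σ_x (PrD_x / E_Sx) · C_x / GFR · 100,000
    GFR  = Σ_x (B_x / E_Rx) · C_x · A_x

where MD_x, PrD_x are weighted maternal and pregnancy-related death counts,
E_Sx the sisters' person-years of exposure, C_x the respondent age
composition, B_x and E_Rx the respondents' own live births and exposure,
and A_x the age-specific denominator adjustment factors built from the
five-year reproductive-calendar outcome distribution:

    A_x(total births)      = (LB_x + SB_x) / LB_x
    A_x(total pregnancies) = (LB_x + SB_x + MSC/AB_x) / LB_x

(stillbirth = pregnancy loss at ≥ 7 months' gestation; all A_x = 1
reproduces the conventional live-birth indicator). Standard errors come
from a stratified delete-one-cluster jackknife with normal-approximation
95% CIs.

Because real sibling-history microdata are access-restricted, the package
includes a synthetic survey generator with known ground-truth rates and
closed-form expected ratios, used to validate the whole pipeline
(parameter recovery and CI coverage).

## Worked example

```sh
python examples/simulate_and_estimate.py
```

prints

```
survey: 1250 respondents, 6292 siblings, 1198 pregnancies
PRMR = 544 per 100,000 live births (jackknife SE 199, 95% CI 155-933); true value under the simulation parameters: 554
MMR = 506 per 100,000 live births (jackknife SE 177, 95% CI 158-854); true value under the simulation parameters: 488
```

A survey of 1,250 women carries only a handful of pregnancy-related sister
deaths, so the CI is wide — the reason real surveys pool seven years of
exposure. The point estimates straddle the analytically expected values.
The other examples show the denominator comparison
(`denominator_comparison.py`: the PRMR falls by ~1.3% with a total-births
denominator and ~10% with total pregnancies under the default outcome
mix), the weighted outcome distribution and A_x table
(`outcome_distribution.py`), and generic re-denomination of a per-live-birth
indicator such as a near-miss ratio (`redenominate_indicator.py`).

A thin CLI wraps the same library:

```sh
matdenom simulate --out survey/
matdenom estimate --survey survey/ --metric prmr --scenario total_births --out est.csv
matdenom compare  --survey survey/ --metric prmr --out cmp.csv
matdenom outcomes --survey survey/ --out outcomes.csv
```

## Layout

- `src/matdenom/` — the library: `data_model` (survey tables, delimited-text
  I/O, validation), `demographic_time` (century-month codes, windows,
  person-years), `adjustment` (outcome classification, A_x),
  `estimation` (rates, GFR, ratio assembly), `variance` (cluster
  jackknife), `synthetic` (generator + expected ratios), `reporting`
  (scenario comparison, re-denomination), `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions, and limitations.
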