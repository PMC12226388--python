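"""Re-denominate any per-live-birth indicator, e.g. a maternal near-miss ratio.

Any maternal indicator expressed per N live births (near-miss ratio,
caesarean rate, ANC coverage, ...) can be converted to a total-births or
total-pregnancies base by dividing by the composition-weighted mean
adjustment factor.
"""

from matdenom import (
    AgeGroupTable,
    Scenario,
    SimulationParams,
    generate_survey,
    outcome_distribution,
    redenominate,
)

survey = generate_survey(SimulationParams(seed=12))
dist = outcome_distribution(survey)

# weight each age group by its share of weighted live births
shares = dist.lb.values / dist.lb.values.sum()
composition = AgeGroupTable(shares)

near_miss = 8.0  # events per 1,000 live births
for scenario in (Scenario.TOTAL_BIRTHS, Scenario.TOTAL_PREGNANCIES):
    adj = redenominate(near_miss, dist, scenario, composition)
    print(f"near-miss ratio: {near_miss:.2f} per 1,000 live births "
          f"-> {adj:.2f} per 1,000 {scenario.value}")

# The denominator grows to include stillbirths (total births) and early
# losses (total pregnancies), so the per-unit indicator value shrinks.
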