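"""Weighted pregnancy-outcome distribution and the adjustment factors A_x.

The five-year reproductive calendar before each interview supplies the
sampling-weighted shares of live births, stillbirths, and early losses by
the mother's age group; the denominator adjustment divides each group's
births-or-pregnancies total by its live births.
"""

from matdenom import (
    AGE_GROUP_LABELS,
    Scenario,
    SimulationParams,
    adjustment_factors,
    generate_survey,
    outcome_distribution,
)

survey = generate_survey(SimulationParams(seed=3))
dist = outcome_distribution(survey, window_years=5)

print("overall weighted shares:",
      ", ".join(f"{k} {100 * v:.1f}%" for k, v in dist.proportions().items()))

tb = adjustment_factors(dist, Scenario.TOTAL_BIRTHS, warn_empty=False)
tp = adjustment_factors(dist, Scenario.TOTAL_PREGNANCIES, warn_empty=False)
print(f"{'group':>6} {'LB':>8} {'SB':>7} {'MSC/AB':>7} {'A_tb':>7} {'A_tp':>7}")
for i, lbl in enumerate(AGE_GROUP_LABELS):
    print(f"{lbl:>6} {dist.lb[i]:8.1f} {dist.sb[i]:7.1f} {dist.msc_ab[i]:7.1f} "
          f"{tb[i]:7.3f} {tp[i]:7.3f}")

# A_tb = (LB+SB)/LB and A_tp = (LB+SB+MSC/AB)/LB per group; multiplying the
# age-specific fertility rates by these factors converts the live-birth
# denominator of any mortality ratio into total births or total pregnancies.
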