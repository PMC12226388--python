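"""Scenario comparison and generic re-denomination of live-birth indicators.

``compare`` re-estimates a mortality ratio under the total-births and
total-pregnancies denominators and reports the absolute (per 100,000) and
relative (%) change against the conventional live-birth denominator. All
three estimates share identical numerator inputs — only the adjustment
factors A_x differ — so any change is attributable to the denominator alone.

``redenominate`` applies the same correction to any indicator expressed per
N live births (near-miss ratios, caesarean rates, ANC coverage, ...): divide
by the composition-weighted mean adjustment factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agegroups import AgeGroupTable
from .adjustment import OutcomeDistribution, Scenario, adjustment_factors
from .data_model import Survey
from .errors import MatdenomError
from .estimation import EstimateConfig, RatioEstimate, aggregate, estimate_from_aggregates

__all__ = ["ScenarioComparison", "compare", "redenominate", "comparisons_frame"]


@dataclass
class ScenarioComparison:
    """An adjusted estimate against the live-birth baseline."""

    metric: str
    baseline: RatioEstimate
    adjusted: RatioEstimate
    absolute_change: float
    relative_change_pct: float


def _comparison(metric: str, baseline: RatioEstimate, adjusted: RatioEstimate) -> ScenarioComparison:
    abs_change = adjusted.value - baseline.value
    rel = 100.0 * abs_change / baseline.value if baseline.value != 0 else float("nan")
    return ScenarioComparison(metric, baseline, adjusted, abs_change, rel)


def compare(
    survey: Survey,
    metric,
    config: EstimateConfig | None = None,
    variance: bool = True,
) -> list[ScenarioComparison]:
    """Estimates under total-births and total-pregnancies vs live births.

    The survey is aggregated once, so the three estimates are guaranteed to
    share numerator inputs; the input survey is never mutated.
    """
    from .data_model import require_valid

    require_valid(survey)
    agg = aggregate(survey, config)
    baseline = estimate_from_aggregates(agg, metric, Scenario.LIVE_BIRTHS, variance=variance)
    out = []
    for scenario in (Scenario.TOTAL_BIRTHS, Scenario.TOTAL_PREGNANCIES):
        adjusted = estimate_from_aggregates(agg, metric, scenario, variance=variance)
        out.append(_comparison(baseline.metric, baseline, adjusted))
    return out


def comparisons_frame(comparisons: list[ScenarioComparison]) -> pd.DataFrame:
    """Long-format table of comparisons for delimited-text export.

    Machine output keeps full float precision; round for display only.
    """
    rows = []
    for c in comparisons:
        rows.append(
            {
                "metric": c.metric,
                "scenario": c.adjusted.scenario.value,
                "baseline": c.baseline.value,
                "baseline_se": c.baseline.se,
                "adjusted": c.adjusted.value,
                "adjusted_se": c.adjusted.se,
                "adjusted_ci_low": c.adjusted.ci_low,
                "adjusted_ci_high": c.adjusted.ci_high,
                "absolute_change": c.absolute_change,
                "relative_change_pct": c.relative_change_pct,
            }
        )
    return pd.DataFrame(rows)


def redenominate(
    indicator_value: float,
    dist: OutcomeDistribution,
    scenario,
    fertility_composition: AgeGroupTable,
) -> float:
    """Convert any per-live-birth indicator to an alternative denominator.

    Divides the indicator by the composition-weighted mean adjustment
    factor sum_x w_x A_x, where the weights w_x (summing to 1) describe the
    share of live births — or of whatever fertility composition applies —
    in each maternal age group. With w_x set to the GFR's group shares this
    reproduces the mortality-ratio pipeline's adjustment exactly.
    """
    scenario = Scenario(scenario)
    w = fertility_composition.values
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise MatdenomError("fertility_composition must be non-negative weights summing to 1")
    a = adjustment_factors(dist, scenario, required_groups=w > 0, warn_empty=False)
    mean_a = float(np.sum(w * a.values))
    return float(indicator_value) / mean_a
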