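"""Discounting, per-cycle cost/utility accrual, and ICER computation.

Costs and QALYs are discounted at 3%/year by default, with the first
cycle undiscounted.  Costs carry a sector tag (formal health care vs
non-health-care); the societal perspective sums both sectors, the
health-care-sector perspective keeps only the formal components
(long-term care and unpaid lost productivity drop out).

Incremental cost-effectiveness ratios are reported as dollars per QALY
gained, with dominance labels when one strategy is both cheaper and
more effective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

from .parameters import (
    CostTable,
    FractureKind,
    Perspective,
    UtilityTable,
)

#: sector assignment of every cost component (impact-inventory style)
COMPONENT_SECTORS: Dict[str, str] = {
    "drug": "formal_health_care",
    "physician_visits": "formal_health_care",
    "dxa": "formal_health_care",
    "fracture_treatment": "formal_health_care",
    "ltc_acute": "non_health_care",
    "ltc_steady": "non_health_care",
    "productivity": "non_health_care",
}


def discount(value: float, cycle_index: int, rate: float) -> float:
    """Discount a value accrued in the given annual cycle (cycle 0 = year 1,
    undiscounted)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return value / (1.0 + rate) ** cycle_index


def perspective_total(components: Mapping[str, float],
                      perspective: Perspective) -> float:
    """Sum cost components under a reporting perspective."""
    if perspective == Perspective.SOCIETAL:
        return float(sum(components.values()))
    if perspective == Perspective.HEALTH_CARE_SECTOR:
        return float(
            sum(v for k, v in components.items()
                if COMPONENT_SECTORS[k] == "formal_health_care")
        )
    raise ValueError(f"unknown perspective {perspective!r}")


def fracture_treatment_cost(kind: FractureKind, costs: CostTable) -> float:
    return costs.fracture_treatment_cost[kind]


def acute_ltc_cost(costs: CostTable) -> float:
    """Six months of long-term-care cost in the hip-fracture year, charged
    to individuals drawn into long-term care, attenuated by the fraction
    of placements attributable to the fracture."""
    return 6.0 * costs.ltc_monthly_cost * costs.ltc_attributable_fraction


def steady_ltc_cost(costs: CostTable) -> float:
    """Population-averaged annual long-term-care cost applied to everyone
    in the post-hip-fracture state."""
    return costs.annual_ltc_cost


def productivity_loss(age: int, costs: CostTable) -> float:
    """Unpaid lost productivity in a hip-fracture year (8 weeks of median
    earnings scaled by the age band's labor-force participation); zero
    beyond age 80."""
    if age < 70:
        band = "65-69"
    elif age < 75:
        band = "70-74"
    elif age <= 80:
        band = "75-80"
    else:
        return 0.0
    return (
        costs.weekly_earnings
        * costs.productivity_weeks
        * costs.labor_participation[band]
    )


def cycle_utility(
    age: int,
    history: Iterable[FractureKind],
    event: FractureKind | None,
    utilities: UtilityTable,
) -> float:
    """Utility accrued over one alive cycle.

    Baseline utility at the current age times the product of the active
    disutility multipliers: the first-year multiplier for a fracture
    sustained this cycle, and the subsequent-year multiplier for every
    fracture type already in the history (1.0 for wrist/other).  A type
    fractured this cycle contributes its first-year multiplier only.
    """
    u = utilities.baseline[age]
    history = set(history)
    for kind in history:
        if kind != event:
            u *= utilities.subsequent_year_multiplier[kind]
    if event is not None:
        u *= utilities.first_year_multiplier[event]
    return u


@dataclass
class StrategyResult:
    """Monte-Carlo summary for one strategy under one perspective."""

    strategy: str
    perspective: Perspective
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se_cost < 0 or self.se_qaly < 0:
            raise ValueError("standard errors must be >= 0")


@dataclass
class ICERResult:
    """Incremental comparison of an intervention vs a comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None  # None when dominance or a zero QALY difference applies
    label: str  # "icer", "dominant", "dominated", or "undefined"

    def cost_effective_at(self, wtp: float) -> bool:
        if self.label == "dominant":
            return True
        if self.label == "dominated":
            return False
        if self.icer is None:
            return self.delta_cost <= 0
        return self.icer <= wtp


def compute_icer(intervention: StrategyResult,
                 comparator: StrategyResult) -> ICERResult:
    """Incremental cost per QALY of ``intervention`` vs ``comparator``.

    A cheaper, more effective intervention is *dominant*; a costlier,
    less effective one is *dominated*.  A zero QALY difference yields an
    undefined ICER.
    """
    dc = intervention.mean_cost - comparator.mean_cost
    de = intervention.mean_qaly - comparator.mean_qaly
    if de == 0.0:
        return ICERResult(delta_cost=dc, delta_qaly=de, icer=None,
                          label="undefined")
    if de > 0 and dc < 0:
        return ICERResult(delta_cost=dc, delta_qaly=de, icer=None,
                          label="dominant")
    if de < 0 and dc > 0:
        return ICERResult(delta_cost=dc, delta_qaly=de, icer=None,
                          label="dominated")
    return ICERResult(delta_cost=dc, delta_qaly=de, icer=dc / de, label="icer")


def round_icer(icer: float) -> float:
    """ICERs are reported to the nearest $100."""
    return round(icer / 100.0) * 100.0


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         wtp: float) -> float:
    """wtp * ΔE - ΔC; non-negative means cost-effective at that threshold."""
    return wtp * delta_qaly - delta_cost
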