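"""Synthetic stand-ins for externally sourced age-indexed inputs.

The published analysis draws its fracture incidence rates, baseline
utilities, disutility multipliers, life table, and osteoporosis risk
modifiers from an earlier technical appendix and vital-statistics
sources that are not part of this package.  The generators here build
structurally equivalent tables — monotone-increasing female mortality,
incidence rising exponentially with age, utility declining linearly
with age — with magnitudes plausible for a high-risk osteoporotic
cohort.  They are deterministic (no RNG), so fixtures are reproducible
by construction, and every generated table passes the validators in
:mod:`osteosim.parameters`.

None of the default values produced here should be read as the
published model's inputs.
"""

from __future__ import annotations

import math
from typing import Dict, Mapping

from pydantic import BaseModel, Field

from .parameters import (
    ALL_FRACTURES,
    MAX_AGE,
    MIN_AGE,
    FractureKind,
    IncidenceTable,
    MortalityTable,
    UtilityTable,
)

F = FractureKind

#: synthetic osteoporosis fracture-risk multipliers (appendix-only input)
DEFAULT_RR_OSTEOPOROSIS: Dict[FractureKind, float] = {
    F.HIP: 2.0,
    F.CLINICAL_VERTEBRAL: 2.0,
    F.WRIST: 1.4,
    F.OTHER: 1.5,
}

#: synthetic lifelong excess-mortality relative risk after hip fracture
#: (appendix-only input; only 25% of the excess is attributed to the fracture)
DEFAULT_HIP_EXCESS_MORTALITY_RR: float = 2.0


class LifeTableSpec(BaseModel):
    """Gompertz mortality: q(age) = min(1, a * exp(b * (age - 65)))."""

    a: float = Field(default=0.011, gt=0)
    b: float = Field(default=0.105, gt=0)
    max_age: int = MAX_AGE


def generate_life_table(spec: LifeTableSpec | None = None) -> MortalityTable:
    """Build a monotone female life table for ages 65..105.

    The default parameters are calibrated so that ≥99.9% of a cohort
    starting at 65 dies by age 105 (see :func:`survival_to_max_age`).
    """
    spec = spec or LifeTableSpec()
    q = {
        age: min(1.0, spec.a * math.exp(spec.b * (age - MIN_AGE)))
        for age in range(MIN_AGE, spec.max_age + 1)
    }
    return MortalityTable(q=q)


def survival_to_max_age(table: MortalityTable, start_age: int = MIN_AGE) -> float:
    """Probability of surviving from ``start_age`` to age 105, by direct
    product of annual survival probabilities."""
    s = 1.0
    for age in range(start_age, MAX_AGE):
        s *= 1.0 - table.q[age]
    return s


#: per-type general-population incidence at age 65 (annual rate) and the
#: exponential age slope; chosen so that with the high-risk modifiers the
#: cohort's lifetime fracture risks are realistic for osteoporotic women
#: with a prior vertebral fracture.
DEFAULT_INCIDENCE_AT_65: Dict[FractureKind, float] = {
    F.HIP: 0.0030,
    F.CLINICAL_VERTEBRAL: 0.0042,
    F.WRIST: 0.0050,
    F.OTHER: 0.0050,
}
DEFAULT_INCIDENCE_SLOPE: Dict[FractureKind, float] = {
    F.HIP: 0.080,
    F.CLINICAL_VERTEBRAL: 0.050,
    F.WRIST: 0.010,
    F.OTHER: 0.040,
}


def generate_incidence_table(
    base_rates_at_65: Mapping[FractureKind, float] | None = None,
    age_slope: Mapping[FractureKind, float] | None = None,
) -> IncidenceTable:
    """Baseline incidence rate(age, kind) = base * exp(slope * (age - 65))."""
    base = dict(base_rates_at_65 or DEFAULT_INCIDENCE_AT_65)
    slope = dict(age_slope or DEFAULT_INCIDENCE_SLOPE)
    rates = {
        kind: {
            age: base[kind] * math.exp(slope[kind] * (age - MIN_AGE))
            for age in range(MIN_AGE, MAX_AGE + 1)
        }
        for kind in ALL_FRACTURES
    }
    return IncidenceTable(rates=rates)


#: synthetic disutility multipliers (appendix-only input): hip and
#: clinical vertebral fractures carry lifelong disutility, wrist/other
#: only a first-year loss.
DEFAULT_FIRST_YEAR_MULTIPLIER: Dict[FractureKind, float] = {
    F.HIP: 0.70,
    F.CLINICAL_VERTEBRAL: 0.80,
    F.WRIST: 0.95,
    F.OTHER: 0.91,
}
DEFAULT_SUBSEQUENT_YEAR_MULTIPLIER: Dict[FractureKind, float] = {
    F.HIP: 0.90,
    F.CLINICAL_VERTEBRAL: 0.95,
    F.WRIST: 1.0,
    F.OTHER: 1.0,
}


def generate_utility_table(
    anchor_at_65: float = 0.81,
    annual_decline: float = 0.004,
    first_year_multiplier: Mapping[FractureKind, float] | None = None,
    subsequent_year_multiplier: Mapping[FractureKind, float] | None = None,
) -> UtilityTable:
    """Baseline utility declining linearly with age, floored above 0."""
    if not (0 < anchor_at_65 <= 1):
        raise ValueError("anchor_at_65 must be in (0, 1]")
    if annual_decline < 0:
        raise ValueError("annual_decline must be >= 0")
    baseline = {
        age: max(1e-6, anchor_at_65 - annual_decline * (age - MIN_AGE))
        for age in range(MIN_AGE, MAX_AGE + 1)
    }
    return UtilityTable(
        baseline=baseline,
        first_year_multiplier=dict(
            first_year_multiplier or DEFAULT_FIRST_YEAR_MULTIPLIER),
        subsequent_year_multiplier=dict(
            subsequent_year_multiplier or DEFAULT_SUBSEQUENT_YEAR_MULTIPLIER),
    )
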