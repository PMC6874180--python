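"""Shared fixtures: the default parameter set and a tiny analytically
tractable model (one fracture type, constant hazards, flat utilities)
used for exhaustive-enumeration cross-checks."""

from __future__ import annotations

import pytest

from osteosim.parameters import (
    MAX_AGE,
    MIN_AGE,
    AdherenceSchedule,
    CostTable,
    Drug,
    EfficacyEntry,
    FractureKind,
    IncidenceTable,
    MortalityTable,
    ParameterSet,
    PricingAssumption,
    RiskModifiers,
    TreatmentPlan,
    UtilityTable,
    default_parameter_set,
)

F = FractureKind
AGES = range(MIN_AGE, MAX_AGE + 1)


@pytest.fixture(scope="session")
def default_ps() -> ParameterSet:
    return default_parameter_set()


def make_toy_params(
    p_fracture: float = 0.1,
    q_death: float = 0.0,
    baseline_utility: float = 0.8,
    first_mult: float = 0.9,
    subseq_mult: float = 0.95,
    fracture_cost: float = 1000.0,
) -> ParameterSet:
    """One active fracture type (clinical vertebral) with a constant
    per-cycle probability, constant mortality, flat utilities, a single
    fracture cost, and no drug/visit/LTC/productivity costs."""
    ones = {k: 1.0 for k in F}
    eff = {
        k: EfficacyEntry(rr_trial=1.0, range_low=1.0, range_high=1.0,
                         distribution="beta")
        for k in F
    }
    sched = AdherenceSchedule(
        persistence_12m=1.0, persistence_24m=1.0,
        adherence_12m=1.0, adherence_24m=1.0)
    return ParameterSet(
        efficacy={Drug.TERIPARATIDE: eff, Drug.ALENDRONATE: dict(eff)},
        adherence={Drug.TERIPARATIDE: sched, Drug.ALENDRONATE: sched},
        plans={
            Drug.TERIPARATIDE: TreatmentPlan(
                drug=Drug.TERIPARATIDE, planned_duration_years=2,
                offset_washout_years=1.0),
            Drug.ALENDRONATE: TreatmentPlan(
                drug=Drug.ALENDRONATE, planned_duration_years=10,
                offset_washout_years=10.0),
        },
        pricing={
            d: PricingAssumption(
                brand_unit_price=0.0, fills_per_year=0, brand_price_factor=0.0,
                generic_discount=0.0, generic_share=1.0)
            for d in Drug
        },
        costs=CostTable(
            annual_drug_cost={d: 0.0 for d in Drug},
            physician_visit_cost=0.0,
            dxa_cost=0.0,
            fracture_treatment_cost={
                F.HIP: 0.0,
                F.CLINICAL_VERTEBRAL: fracture_cost,
                F.WRIST: 0.0,
                F.OTHER: 0.0,
            },
            ltc_monthly_cost=0.0,
            ltc_stay_fraction=0.0,
            ltc_attributable_fraction=0.0,
            weekly_earnings=0.0,
            productivity_weeks=0.0,
            labor_participation={"65-69": 0.0, "70-74": 0.0, "75-80": 0.0},
        ),
        risks=RiskModifiers(
            rr_prior_vertebral=dict(ones),
            rr_osteoporosis=dict(ones),
            hip_excess_mortality_rr=1.0,
            excess_attributable_fraction=0.25,
        ),
        utilities=UtilityTable(
            baseline={a: baseline_utility for a in AGES},
            first_year_multiplier={
                F.HIP: 1.0, F.CLINICAL_VERTEBRAL: first_mult,
                F.WRIST: 1.0, F.OTHER: 1.0},
            subsequent_year_multiplier={
                F.HIP: 1.0, F.CLINICAL_VERTEBRAL: subseq_mult,
                F.WRIST: 1.0, F.OTHER: 1.0},
        ),
        mortality=MortalityTable(q={a: q_death for a in AGES}),
        incidence=IncidenceTable(rates={
            k: {a: (p_fracture if k == F.CLINICAL_VERTEBRAL else 0.0)
                for a in AGES}
            for k in F
        }),
    )


@pytest.fixture
def toy_params() -> ParameterSet:
    return make_toy_params()
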