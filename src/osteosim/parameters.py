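"""Model parameter types, validation, defaults, and file I/O.

Every input the simulation consumes lives in a :class:`ParameterSet`:
treatment efficacy (trial relative risks vs placebo per fracture type),
real-world persistence/adherence schedules, drug pricing assumptions,
unit costs by sector, fracture-risk modifiers for the high-risk cohort,
age-indexed baseline utilities and fracture disutility multipliers, an
age-indexed female life table, and age-indexed baseline fracture
incidence rates.

Values printed in the source cost and parameter tables (efficacy RRs,
persistence/adherence, unit costs, relative risks for prior vertebral
fracture) are encoded verbatim in :func:`default_parameter_set`.
Age-indexed tables (incidence, utilities, mortality) and the
osteoporosis risk modifiers are available only from external sources,
so the defaults are synthetic stand-ins built by
:mod:`osteosim.synthetic`; they are plausible for a high-risk
osteoporotic cohort but are not the published values.
"""

from __future__ import annotations

import copy
from enum import Enum
from pathlib import Path
from typing import Dict, Literal, Mapping, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator


class FractureKind(str, Enum):
    """The four osteoporotic fracture types tracked by the model."""

    HIP = "hip"
    CLINICAL_VERTEBRAL = "clinical_vertebral"
    WRIST = "wrist"
    OTHER = "other_osteoporotic"


ALL_FRACTURES: Tuple[FractureKind, ...] = tuple(FractureKind)


class Drug(str, Enum):
    TERIPARATIDE = "teriparatide"
    ALENDRONATE = "alendronate"


class Strategy(str, Enum):
    SEQUENTIAL = "sequential"
    ALENDRONATE_ALONE = "alendronate_alone"
    NO_TREATMENT = "no_treatment"


class Perspective(str, Enum):
    SOCIETAL = "societal"
    HEALTH_CARE_SECTOR = "health_care_sector"


#: minimum / maximum age covered by every age-indexed table
MIN_AGE = 65
MAX_AGE = 105

DistributionKind = Literal["beta", "triangular", "log_normal", "gamma", "point_mass"]


class DistributionSpec(BaseModel):
    """An uncertain parameter: central value plus a (low, high) range.

    ``kind`` selects the sampling family used in probabilistic
    sensitivity analysis (see :func:`osteosim.sensitivity.sample_parameter`).
    """

    kind: DistributionKind
    base: float
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "DistributionSpec":
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"distribution requires low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        return self


class EfficacyEntry(BaseModel):
    """Trial relative risk of one fracture type vs placebo for one drug."""

    rr_trial: float = Field(gt=0)
    range_low: float
    range_high: float
    distribution: Literal["beta", "triangular"]

    @model_validator(mode="after")
    def _in_range(self) -> "EfficacyEntry":
        if not (self.range_low <= self.rr_trial <= self.range_high):
            raise ValueError(
                f"rr_trial {self.rr_trial} outside range "
                f"[{self.range_low}, {self.range_high}]"
            )
        return self


class AdherenceSchedule(BaseModel):
    """Real-world persistence and adherence at 12/24 months (fractions).

    Beyond 24 months both decline linearly on the 12->24-month slope up
    to 60 months (clamped at 0) and stay flat thereafter.
    """

    persistence_12m: float = Field(ge=0, le=1)
    persistence_24m: float = Field(ge=0, le=1)
    adherence_12m: float = Field(ge=0, le=1)
    adherence_24m: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _monotone(self) -> "AdherenceSchedule":
        if self.persistence_24m > self.persistence_12m:
            raise ValueError("persistence_24m must not exceed persistence_12m")
        if self.adherence_24m > self.adherence_12m:
            raise ValueError("adherence_24m must not exceed adherence_12m")
        return self


class TreatmentPlan(BaseModel):
    """Planned course for one drug and the post-course washout window."""

    drug: Drug
    planned_duration_years: int = Field(gt=0)
    offset_washout_years: float = Field(ge=0)
    trial_adherence_reference: float = Field(default=0.80, gt=0, le=1)


class PricingAssumption(BaseModel):
    """How the annual cost of one drug is built from list prices.

    ``brand_annual = brand_unit_price * fills_per_year * brand_price_factor``.
    The generic/biosimilar annual cost comes either from its own unit
    price (alendronate: a separate AWP with its own payment factor) or
    from a discount off the brand annual cost (teriparatide).  The
    blended annual cost mixes the two by ``generic_share``.
    """

    brand_unit_price: float = Field(ge=0)
    fills_per_year: int = Field(ge=0)
    brand_price_factor: float = Field(ge=0)
    generic_unit_price: float | None = None
    generic_price_factor: float | None = None
    generic_discount: float | None = Field(default=None, ge=0, le=1)
    generic_share: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _generic_defined(self) -> "PricingAssumption":
        has_unit = self.generic_unit_price is not None
        if has_unit and self.generic_price_factor is None:
            raise ValueError("generic_unit_price requires generic_price_factor")
        if not has_unit and self.generic_discount is None:
            raise ValueError(
                "either generic_unit_price/factor or generic_discount required"
            )
        return self


class CostTable(BaseModel):
    """Unit costs (2018 USD) with their sector assignment.

    Formal-health-care components: drugs, physician visits, DXA scans,
    fracture treatment.  Non-health-care components: long-term care
    after hip fracture and unpaid lost productivity.  The latter are
    dropped under the health-care-sector perspective.
    """

    annual_drug_cost: Dict[Drug, float]
    physician_visit_cost: float = Field(ge=0)
    dxa_cost: float = Field(ge=0)
    fracture_treatment_cost: Dict[FractureKind, float]
    ltc_monthly_cost: float = Field(ge=0)
    ltc_stay_fraction: float = Field(ge=0, le=1)
    ltc_attributable_fraction: float = Field(ge=0, le=1)
    weekly_earnings: float = Field(ge=0)
    productivity_weeks: float = Field(ge=0)
    labor_participation: Dict[str, float]  # keys "65-69", "70-74", "75-80"

    @model_validator(mode="after")
    def _complete(self) -> "CostTable":
        _require_all_fractures(self.fracture_treatment_cost, "fracture_treatment_cost")
        for d in Drug:
            if d not in self.annual_drug_cost:
                raise ValueError(f"annual_drug_cost missing {d.value}")
        for key in ("65-69", "70-74", "75-80"):
            if key not in self.labor_participation:
                raise ValueError(f"labor_participation missing band {key}")
        for name, mapping in (
            ("annual_drug_cost", self.annual_drug_cost),
            ("fracture_treatment_cost", self.fracture_treatment_cost),
        ):
            for k, v in mapping.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] negative")
        for k, v in self.labor_participation.items():
            if not (0 <= v <= 1):
                raise ValueError(f"labor_participation[{k}] outside [0,1]")
        return self

    @property
    def annual_ltc_cost(self) -> float:
        """Population-averaged yearly long-term-care cost in the post-hip state."""
        return (
            self.ltc_monthly_cost
            * 12.0
            * self.ltc_stay_fraction
            * self.ltc_attributable_fraction
        )


class RiskModifiers(BaseModel):
    """Multiplicative fracture-risk elevation for the modelled cohort.

    Prior vertebral fracture and densitometric osteoporosis each raise
    baseline general-population incidence multiplicatively.  Hip
    fractures carry lifelong excess mortality, of which only
    ``excess_attributable_fraction`` (25%) is attributed to the
    fracture itself.
    """

    rr_prior_vertebral: Dict[FractureKind, float]
    rr_osteoporosis: Dict[FractureKind, float]
    hip_excess_mortality_rr: float = Field(ge=1)
    excess_attributable_fraction: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _valid(self) -> "RiskModifiers":
        for name, mapping in (
            ("rr_prior_vertebral", self.rr_prior_vertebral),
            ("rr_osteoporosis", self.rr_osteoporosis),
        ):
            _require_all_fractures(mapping, name)
            for k, v in mapping.items():
                if v < 1:
                    raise ValueError(f"{name}[{k.value}] = {v} < 1")
        return self


class UtilityTable(BaseModel):
    """Age-indexed baseline utility and fracture disutility multipliers.

    Hip and clinical vertebral fractures reduce utility most in the
    first post-fracture year and permanently thereafter; wrist and
    other fractures only in the first year (subsequent multiplier 1.0).
    """

    baseline: Dict[int, float]
    first_year_multiplier: Dict[FractureKind, float]
    subsequent_year_multiplier: Dict[FractureKind, float]

    @model_validator(mode="after")
    def _valid(self) -> "UtilityTable":
        _require_age_range(self.baseline, "baseline utility")
        for age, u in self.baseline.items():
            if not (0 < u <= 1):
                raise ValueError(f"baseline utility at age {age} = {u} not in (0,1]")
        for name, mapping in (
            ("first_year_multiplier", self.first_year_multiplier),
            ("subsequent_year_multiplier", self.subsequent_year_multiplier),
        ):
            _require_all_fractures(mapping, name)
            for k, v in mapping.items():
                if not (0 < v <= 1):
                    raise ValueError(f"{name}[{k.value}] = {v} not in (0,1]")
        for kind in (FractureKind.WRIST, FractureKind.OTHER):
            if self.subsequent_year_multiplier[kind] != 1.0:
                raise ValueError(
                    f"subsequent_year_multiplier[{kind.value}] must be 1.0 "
                    "(no disutility beyond the first year)"
                )
        return self


class MortalityTable(BaseModel):
    """Annual death probability q(age) for ages 65..105, non-decreasing."""

    q: Dict[int, float]

    @model_validator(mode="after")
    def _valid(self) -> "MortalityTable":
        _require_age_range(self.q, "mortality q")
        prev = -1.0
        for age in range(MIN_AGE, MAX_AGE + 1):
            v = self.q[age]
            if not (0 <= v <= 1):
                raise ValueError(f"q({age}) = {v} outside [0,1]")
            if v < prev:
                raise ValueError(f"q({age}) decreases with age")
            prev = v
        return self


class IncidenceTable(BaseModel):
    """Baseline annual fracture incidence per type per age (general population)."""

    rates: Dict[FractureKind, Dict[int, float]]

    @model_validator(mode="after")
    def _valid(self) -> "IncidenceTable":
        _require_all_fractures(self.rates, "incidence rates")
        for kind, table in self.rates.items():
            _require_age_range(table, f"incidence[{kind.value}]")
            for age, r in table.items():
                if r < 0:
                    raise ValueError(f"incidence[{kind.value}]({age}) negative")
        return self


class ScenarioConfig(BaseModel):
    """One simulation run: cohort, strategy, horizon, discounting, seeds."""

    start_age: int = 65
    strategy: Strategy = Strategy.SEQUENTIAL
    horizon_end_age: int = MAX_AGE
    discount_rate: float = Field(default=0.03, ge=0, lt=1)
    perspective: Perspective = Perspective.SOCIETAL
    wtp_thresholds: Tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0)
    n_individuals: int = Field(default=100_000, ge=1)
    master_seed: int = 0
    common_random_numbers: bool = True

    @model_validator(mode="after")
    def _valid(self) -> "ScenarioConfig":
        if not (MIN_AGE <= self.start_age < self.horizon_end_age <= MAX_AGE):
            raise ValueError(
                f"need {MIN_AGE} <= start_age < horizon_end_age <= {MAX_AGE}"
            )
        return self


class ParameterSet(BaseModel):
    """The complete, validated model input bundle."""

    efficacy: Dict[Drug, Dict[FractureKind, EfficacyEntry]]
    adherence: Dict[Drug, AdherenceSchedule]
    plans: Dict[Drug, TreatmentPlan]
    pricing: Dict[Drug, PricingAssumption]
    costs: CostTable
    risks: RiskModifiers
    utilities: UtilityTable
    mortality: MortalityTable
    incidence: IncidenceTable
    uncertainty: Dict[str, DistributionSpec] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _valid(self) -> "ParameterSet":
        for d in Drug:
            for coll, name in (
                (self.efficacy, "efficacy"),
                (self.adherence, "adherence"),
                (self.plans, "plans"),
                (self.pricing, "pricing"),
            ):
                if d not in coll:
                    raise ValueError(f"{name} missing drug {d.value}")
            _require_all_fractures(self.efficacy[d], f"efficacy[{d.value}]")
        # modified per-type event probability must stay below 1 at every age
        for kind in ALL_FRACTURES:
            mod = self.risks.rr_prior_vertebral[kind] * self.risks.rr_osteoporosis[kind]
            for age in range(MIN_AGE, MAX_AGE + 1):
                p = self.incidence.rates[kind][age] * mod
                if p >= 1.0:
                    raise ValueError(
                        f"modified incidence for {kind.value} at age {age} is "
                        f"{p:.3f} >= 1"
                    )
        return self


def _require_all_fractures(mapping: Mapping, name: str) -> None:
    for kind in ALL_FRACTURES:
        if kind not in mapping:
            raise ValueError(f"{name} missing fracture kind {kind.value}")


def _require_age_range(table: Mapping[int, float], name: str) -> None:
    for age in range(MIN_AGE, MAX_AGE + 1):
        if age not in table:
            raise ValueError(f"{name} missing age {age}")


# ---------------------------------------------------------------------------
# defaults


def default_parameter_set() -> ParameterSet:
    """Build the shipped default :class:`ParameterSet`.

    Printed-table values (efficacy, persistence/adherence, costs, prior
    vertebral fracture RRs, pricing primitives) are encoded verbatim;
    age-indexed tables and osteoporosis RRs are synthetic defaults from
    :mod:`osteosim.synthetic`.
    """
    from . import pricing as _pricing
    from . import synthetic

    F = FractureKind
    teri_eff = {
        F.HIP: EfficacyEntry(rr_trial=0.42, range_low=0.10, range_high=1.0,
                             distribution="triangular"),
        F.CLINICAL_VERTEBRAL: EfficacyEntry(rr_trial=0.30, range_low=0.16,
                                            range_high=0.55, distribution="beta"),
        F.WRIST: EfficacyEntry(rr_trial=0.24, range_low=0.02, range_high=1.0,
                               distribution="triangular"),
        F.OTHER: EfficacyEntry(rr_trial=0.50, range_low=0.32, range_high=0.78,
                               distribution="beta"),
    }
    alen_eff = {
        F.HIP: EfficacyEntry(rr_trial=0.45, range_low=0.27, range_high=0.68,
                             distribution="beta"),
        F.CLINICAL_VERTEBRAL: EfficacyEntry(rr_trial=0.50, range_low=0.33,
                                            range_high=0.79, distribution="beta"),
        F.WRIST: EfficacyEntry(rr_trial=0.82, range_low=0.25, range_high=1.0,
                               distribution="triangular"),
        F.OTHER: EfficacyEntry(rr_trial=0.78, range_low=0.66, range_high=0.92,
                               distribution="beta"),
    }
    teri_adh = AdherenceSchedule(
        persistence_12m=0.634, persistence_24m=0.408,
        adherence_12m=0.544, adherence_24m=0.398,
    )
    alen_adh = AdherenceSchedule(
        persistence_12m=0.387, persistence_24m=0.237,
        adherence_12m=0.313, adherence_24m=0.228,
    )
    plans = {
        Drug.TERIPARATIDE: TreatmentPlan(
            drug=Drug.TERIPARATIDE, planned_duration_years=2,
            offset_washout_years=1.0,
        ),
        Drug.ALENDRONATE: TreatmentPlan(
            drug=Drug.ALENDRONATE, planned_duration_years=10,
            offset_washout_years=10.0,
        ),
    }
    pricing = {
        # weekly generic tablet at 27% of AWP; brand tablet at 64% of AWP
        Drug.ALENDRONATE: PricingAssumption(
            brand_unit_price=38.3525, fills_per_year=52, brand_price_factor=0.64,
            generic_unit_price=6.13833, generic_price_factor=0.27,
            generic_share=0.90,
        ),
        # 28-day pen at 62% of WAC; generic/biosimilar 30% below brand
        Drug.TERIPARATIDE: PricingAssumption(
            brand_unit_price=3426.50, fills_per_year=13, brand_price_factor=0.62,
            generic_discount=0.30, generic_share=0.90,
        ),
    }
    annual_costs = {
        d: _pricing.blended_annual_cost_from_assumption(pricing[d]) for d in Drug
    }
    costs = CostTable(
        annual_drug_cost=annual_costs,
        physician_visit_cost=74.0,
        dxa_cost=100.0,
        fracture_treatment_cost={
            F.HIP: 29_986.0,
            F.CLINICAL_VERTEBRAL: 8_325.0,
            F.WRIST: 4_577.0,
            F.OTHER: 14_144.0,
        },
        ltc_monthly_cost=7_159.0,
        ltc_stay_fraction=0.12,
        ltc_attributable_fraction=0.25,
        weekly_earnings=757.0,
        productivity_weeks=8.0,
        labor_participation={"65-69": 0.279, "70-74": 0.166, "75-80": 0.059},
    )
    risks = RiskModifiers(
        rr_prior_vertebral={F.HIP: 2.3, F.CLINICAL_VERTEBRAL: 4.4,
                            F.WRIST: 1.4, F.OTHER: 1.8},
        rr_osteoporosis=synthetic.DEFAULT_RR_OSTEOPOROSIS,
        hip_excess_mortality_rr=synthetic.DEFAULT_HIP_EXCESS_MORTALITY_RR,
        excess_attributable_fraction=0.25,
    )
    ps = ParameterSet(
        efficacy={Drug.TERIPARATIDE: teri_eff, Drug.ALENDRONATE: alen_eff},
        adherence={Drug.TERIPARATIDE: teri_adh, Drug.ALENDRONATE: alen_adh},
        plans=plans,
        pricing=pricing,
        costs=costs,
        risks=risks,
        utilities=synthetic.generate_utility_table(),
        mortality=synthetic.generate_life_table(),
        incidence=synthetic.generate_incidence_table(),
        uncertainty={},
    )
    ps.uncertainty.update(default_uncertainty(ps))
    return ps


def default_uncertainty(ps: ParameterSet) -> Dict[str, DistributionSpec]:
    """Distribution specs for every uncertain printed-table row, keyed by
    the dotted parameter path used by :func:`set_by_path`."""
    F = FractureKind
    specs: Dict[str, DistributionSpec] = {}
    for drug in Drug:
        for kind in ALL_FRACTURES:
            e = ps.efficacy[drug][kind]
            specs[f"efficacy.{drug.value}.{kind.value}.rr_trial"] = DistributionSpec(
                kind=e.distribution, base=e.rr_trial,
                low=e.range_low, high=e.range_high,
            )
        sched = ps.adherence[drug]
        for field in ("persistence_12m", "persistence_24m",
                      "adherence_12m", "adherence_24m"):
            base = getattr(sched, field)
            specs[f"adherence.{drug.value}.{field}"] = DistributionSpec(
                kind="triangular", base=base,
                low=0.5 * base, high=min(1.0, 1.5 * base),
            )
    specs["costs.annual_drug_cost.alendronate"] = DistributionSpec(
        kind="triangular", base=ps.costs.annual_drug_cost[Drug.ALENDRONATE],
        low=86.0, high=324.0,
    )
    specs["costs.annual_drug_cost.teriparatide"] = DistributionSpec(
        kind="triangular", base=ps.costs.annual_drug_cost[Drug.TERIPARATIDE],
        low=4005.0, high=22_646.0,
    )
    specs["costs.dxa_cost"] = DistributionSpec(
        kind="triangular", base=100.0, low=49.0, high=150.0)
    for kind, (low, high) in {
        F.HIP: (25_677.0, 42_913.0),
        F.CLINICAL_VERTEBRAL: (5_775.0, 15_975.0),
        F.WRIST: (2_543.0, 10_674.0),
        F.OTHER: (10_086.0, 26_314.0),
    }.items():
        specs[f"costs.fracture_treatment_cost.{kind.value}"] = DistributionSpec(
            kind="log_normal", base=ps.costs.fracture_treatment_cost[kind],
            low=low, high=high,
        )
    specs["costs.ltc_monthly_cost"] = DistributionSpec(
        kind="triangular", base=ps.costs.ltc_monthly_cost,
        low=0.0, high=2 * ps.costs.ltc_monthly_cost,
    )
    for band in ("65-69", "70-74", "75-80"):
        base = ps.costs.labor_participation[band]
        specs[f"costs.labor_participation.{band}"] = DistributionSpec(
            kind="triangular", base=base, low=0.5 * base, high=1.5 * base,
        )
    for kind, (low, high) in {
        F.HIP: (2.0, 2.8),
        F.CLINICAL_VERTEBRAL: (3.6, 5.4),
        F.WRIST: (1.2, 2.7),
        F.OTHER: (1.7, 1.9),
    }.items():
        specs[f"risks.rr_prior_vertebral.{kind.value}"] = DistributionSpec(
            kind="gamma", base=ps.risks.rr_prior_vertebral[kind],
            low=low, high=high,
        )
    return specs


# ---------------------------------------------------------------------------
# dotted-path access (used by one-way and probabilistic sensitivity analysis)


def _coerce_key(mapping: Mapping, key: str):
    if key in mapping:
        return key
    for enum_cls in (Drug, FractureKind):
        try:
            candidate = enum_cls(key)
        except ValueError:
            continue
        if candidate in mapping:
            return candidate
    try:
        as_int = int(key)
    except ValueError:
        pass
    else:
        if as_int in mapping:
            return as_int
    raise KeyError(key)


def get_by_path(ps: ParameterSet, path: str):
    """Read one scalar addressed by a dotted path, e.g.
    ``"efficacy.teriparatide.hip.rr_trial"``."""
    obj = ps
    for part in path.split("."):
        if isinstance(obj, BaseModel):
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter path segment {part!r} in {path!r}")
            obj = getattr(obj, part)
        elif isinstance(obj, Mapping):
            obj = obj[_coerce_key(obj, part)]
        else:
            raise KeyError(f"cannot descend into {type(obj).__name__} at {part!r}")
    return obj


def _assign_path(root: ParameterSet, path: str, value: float) -> None:
    parts = path.split(".")
    obj = root
    for part in parts[:-1]:
        if isinstance(obj, BaseModel):
            if not hasattr(obj, part):
                raise KeyError(f"unknown parameter path segment {part!r} in {path!r}")
            obj = getattr(obj, part)
        elif isinstance(obj, Mapping):
            obj = obj[_coerce_key(obj, part)]
        else:
            raise KeyError(f"cannot descend into {type(obj).__name__} at {part!r}")
    leaf = parts[-1]
    if isinstance(obj, BaseModel):
        if not hasattr(obj, leaf):
            raise KeyError(f"unknown parameter path leaf {leaf!r} in {path!r}")
        object.__setattr__(obj, leaf, value)
    elif isinstance(obj, Mapping):
        obj[_coerce_key(obj, leaf)] = value  # type: ignore[index]
    else:
        raise KeyError(f"cannot assign into {type(obj).__name__}")


def set_by_path(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a new validated ParameterSet with one scalar replaced."""
    return set_many_by_path(ps, {path: value})


def set_many_by_path(ps: ParameterSet,
                     substitutions: Mapping[str, float]) -> ParameterSet:
    """Return a new validated ParameterSet with several scalars replaced
    (one deep copy and one validation pass for the whole batch)."""
    new = copy.deepcopy(ps)
    for path, value in substitutions.items():
        _assign_path(new, path, value)
    # re-run every validator on the mutated tree
    return ParameterSet.model_validate(new.model_dump())


# ---------------------------------------------------------------------------
# file I/O


_AGE_TABLES = {
    "mortality.csv": "mortality",
    "baseline_utility.csv": "baseline_utility",
}
_KIND_TABLES = {
    "first_year_disutility.csv": "first_year_multiplier",
    "subsequent_year_disutility.csv": "subsequent_year_multiplier",
}


def save_parameter_set(ps: ParameterSet, config_path: str | Path,
                       tables_dir: str | Path) -> None:
    """Write a ParameterSet as a YAML config plus CSV tables.

    Age-indexed tables go to ``tables_dir`` as two-column CSVs
    (``age,value``); per-fracture disutility multipliers as
    ``fracture_kind,value``; everything else into the YAML config.
    """
    tables_dir = Path(tables_dir)
    tables_dir.mkdir(parents=True, exist_ok=True)
    data = ps.model_dump(mode="json")
    mortality = data.pop("mortality")["q"]
    utilities = data.pop("utilities")
    incidence = data.pop("incidence")["rates"]

    pd.DataFrame(
        {"age": [int(a) for a in mortality], "value": list(mortality.values())}
    ).to_csv(tables_dir / "mortality.csv", index=False)
    baseline = utilities["baseline"]
    pd.DataFrame(
        {"age": [int(a) for a in baseline], "value": list(baseline.values())}
    ).to_csv(tables_dir / "baseline_utility.csv", index=False)
    for fname, field in _KIND_TABLES.items():
        table = utilities[field]
        pd.DataFrame(
            {"fracture_kind": list(table), "value": list(table.values())}
        ).to_csv(tables_dir / fname, index=False)
    for kind in ALL_FRACTURES:
        table = incidence[kind.value]
        pd.DataFrame(
            {"age": [int(a) for a in table], "value": list(table.values())}
        ).to_csv(tables_dir / f"incidence_{kind.value}.csv", index=False)

    with open(config_path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_parameter_set(config_path: str | Path,
                       tables_dir: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet written by :func:`save_parameter_set`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    (from validation) naming the offending field for any invariant
    violation.
    """
    tables_dir = Path(tables_dir)
    with open(config_path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {config_path} did not parse to a mapping")

    def read_age_csv(fname: str) -> Dict[int, float]:
        df = pd.read_csv(tables_dir / fname, float_precision="round_trip")
        return {int(a): float(v) for a, v in zip(df["age"], df["value"])}

    def read_kind_csv(fname: str) -> Dict[str, float]:
        df = pd.read_csv(tables_dir / fname, float_precision="round_trip")
        return {str(k): float(v) for k, v in zip(df["fracture_kind"], df["value"])}

    data["mortality"] = {"q": read_age_csv("mortality.csv")}
    data["utilities"] = {
        "baseline": read_age_csv("baseline_utility.csv"),
        "first_year_multiplier": read_kind_csv("first_year_disutility.csv"),
        "subsequent_year_multiplier": read_kind_csv("subsequent_year_disutility.csv"),
    }
    data["incidence"] = {
        "rates": {
            kind.value: read_age_csv(f"incidence_{kind.value}.csv")
            for kind in ALL_FRACTURES
        }
    }
    return ParameterSet.model_validate(data)
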