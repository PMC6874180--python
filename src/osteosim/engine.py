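"""Individual-level Markov microsimulation engine.

Women are simulated one at a time through annual cycles from the start
age until death or age 105.  Each cycle, in order: a death draw (with
lifelong excess mortality after hip fracture, of which only 25% is
attributed to the fracture), at most one fracture draw among the four
types (hip fractures capped at two per lifetime), tracker and
treatment-status updates, and cost/utility accrual discounted to the
start of the simulation.

Treatment raises no per-cycle randomness beyond a single persistence
draw per course: the discontinuation time is sampled once at course
start by inverting the persistence curve, which fixes the whole
on-treatment / offset timeline for that individual.  Protection in a
cycle applies only if the individual persists to the cycle's end;
after stopping, the effective relative risk fades linearly back to 1
over a washout window proportional to the completed fraction of the
course (evaluated at mid-cycle).  When several sources of protection
overlap (e.g. the teriparatide offset during alendronate years) the
strongest applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import adherence as adh
from . import economics as econ
from .parameters import (
    ALL_FRACTURES,
    Drug,
    FractureKind,
    ParameterSet,
    Perspective,
    ScenarioConfig,
    Strategy,
)

_KIND_INDEX = {kind: i for i, kind in enumerate(ALL_FRACTURES)}
_HIP = _KIND_INDEX[FractureKind.HIP]

#: named RNG substreams fanned out from the master seed
STREAM_BASE_CASE = 0
STREAM_PSA = 1

#: maximum courses in any strategy (uniform draws are pre-allocated so
#: that common random numbers stay aligned across strategies)
_MAX_COURSES = 2

_STRATEGY_COURSES: Dict[Strategy, Tuple[Drug, ...]] = {
    Strategy.SEQUENTIAL: (Drug.TERIPARATIDE, Drug.ALENDRONATE),
    Strategy.ALENDRONATE_ALONE: (Drug.ALENDRONATE,),
    Strategy.NO_TREATMENT: (),
}


# ---------------------------------------------------------------------------
# small pure helpers (unit-testable pieces of a cycle)


def fracture_probability(
    age: int,
    kind: FractureKind,
    params: ParameterSet,
    treatment_rr: float = 1.0,
    hip_fracture_count: int = 0,
) -> float:
    """Per-cycle fracture probability for one type.

    Baseline general-population incidence at the current age times the
    multiplicative risk elevations for prior vertebral fracture and
    osteoporosis, times the effective treatment relative risk; clamped
    to [0, 1].  Hip probability is zero once two hip fractures have
    occurred.
    """
    table = params.incidence.rates[kind]
    if age not in table:
        raise ValueError(f"age {age} outside incidence table")
    if kind == FractureKind.HIP and hip_fracture_count >= 2:
        return 0.0
    p = (
        table[age]
        * params.risks.rr_prior_vertebral[kind]
        * params.risks.rr_osteoporosis[kind]
        * treatment_rr
    )
    return min(1.0, max(0.0, p))


def mortality_probability(age: int, post_hip: bool,
                          params: ParameterSet) -> float:
    """Annual death probability; after a hip fracture the excess relative
    risk applies only through its attributable fraction:
    q' = q * (1 + f * (RR - 1))."""
    if age not in params.mortality.q:
        raise ValueError(f"age {age} outside mortality table")
    q = params.mortality.q[age]
    if post_hip:
        rr = params.risks.hip_excess_mortality_rr
        f = params.risks.excess_attributable_fraction
        q = q * (1.0 + f * (rr - 1.0))
    return min(1.0, q)


def draw_cycle_event(
    probabilities: Sequence[float],
    u_any: float,
    u_kind: float,
) -> Optional[int]:
    """Draw at most one fracture from competing per-type probabilities.

    The any-fracture probability is 1 - prod(1 - p_k); conditional on a
    fracture, the type is chosen proportional to p_k.  Returns the type
    index or None.
    """
    p = np.asarray(probabilities, dtype=float)
    any_p = 1.0 - np.prod(1.0 - p)
    if any_p <= 0.0 or u_any >= any_p:
        return None
    total = p.sum()
    cum = np.cumsum(p) / total
    return int(np.searchsorted(cum, u_kind, side="right"))


# ---------------------------------------------------------------------------
# compiled inputs


@dataclass
class _Course:
    drug: Drug
    duration: int
    washout: float
    annual_cost: float
    visits_per_year: int
    dxa_years: frozenset
    schedule: object  # AdherenceSchedule
    rr_by_year: np.ndarray  # (duration+1, 4); row 0 = no effect
    adherence_by_year: np.ndarray  # (duration+1,)


@dataclass
class _Compiled:
    start_age: int
    ncycles: int
    discount_rate: float
    q: np.ndarray  # (ncycles,)
    base_p: np.ndarray  # (ncycles, 4) modified incidence before treatment
    baseline_u: np.ndarray  # (ncycles,)
    frac_cost: np.ndarray  # (4,)
    first_mult: np.ndarray  # (4,)
    subseq_mult: np.ndarray  # (4,)
    disc: np.ndarray  # (ncycles,)
    acute_ltc: float
    steady_ltc: float
    ltc_stay_fraction: float
    excess_factor: float  # 1 + f * (RR - 1)
    prod_loss_by_cycle: np.ndarray  # (ncycles,)
    courses: Tuple[_Course, ...]
    visit_cost: float
    dxa_cost: float


def _compile(params: ParameterSet, scenario: ScenarioConfig) -> _Compiled:
    start = scenario.start_age
    ncycles = scenario.horizon_end_age - start
    ages = np.arange(start, start + ncycles)
    q = np.array([params.mortality.q[a] for a in ages])
    base_p = np.empty((ncycles, 4))
    for kind, j in _KIND_INDEX.items():
        mod = (params.risks.rr_prior_vertebral[kind]
               * params.risks.rr_osteoporosis[kind])
        base_p[:, j] = [params.incidence.rates[kind][a] * mod for a in ages]
    baseline_u = np.array([params.utilities.baseline[a] for a in ages])
    frac_cost = np.array(
        [params.costs.fracture_treatment_cost[k] for k in ALL_FRACTURES])
    first_mult = np.array(
        [params.utilities.first_year_multiplier[k] for k in ALL_FRACTURES])
    subseq_mult = np.array(
        [params.utilities.subsequent_year_multiplier[k] for k in ALL_FRACTURES])
    disc = (1.0 + scenario.discount_rate) ** (-np.arange(ncycles, dtype=float))
    prod_loss = np.array(
        [econ.productivity_loss(int(a), params.costs) for a in ages])

    courses: List[_Course] = []
    for drug in _STRATEGY_COURSES[scenario.strategy]:
        plan = params.plans[drug]
        sched = params.adherence[drug]
        dur = plan.planned_duration_years
        rr_by_year = np.ones((dur + 1, 4))
        adh_by_year = np.zeros(dur + 1)
        for y in range(1, dur + 1):
            a = adh.adherence_at(sched, y)
            adh_by_year[y] = a
            f = adh.efficacy_scaling_factor(a, plan.trial_adherence_reference)
            for kind, j in _KIND_INDEX.items():
                rr_by_year[y, j] = adh.community_rr(
                    params.efficacy[drug][kind].rr_trial, f)
        dxa = (frozenset({2}) if drug == Drug.TERIPARATIDE
               else frozenset({5, 10}))
        courses.append(_Course(
            drug=drug,
            duration=dur,
            washout=plan.offset_washout_years,
            annual_cost=params.costs.annual_drug_cost[drug],
            visits_per_year=2 if drug == Drug.TERIPARATIDE else 1,
            dxa_years=dxa,
            schedule=sched,
            rr_by_year=rr_by_year,
            adherence_by_year=adh_by_year,
        ))

    rm = params.risks
    return _Compiled(
        start_age=start,
        ncycles=ncycles,
        discount_rate=scenario.discount_rate,
        q=q,
        base_p=base_p,
        baseline_u=baseline_u,
        frac_cost=frac_cost,
        first_mult=first_mult,
        subseq_mult=subseq_mult,
        disc=disc,
        acute_ltc=econ.acute_ltc_cost(params.costs),
        steady_ltc=econ.steady_ltc_cost(params.costs),
        ltc_stay_fraction=params.costs.ltc_stay_fraction,
        excess_factor=1.0 + rm.excess_attributable_fraction
        * (rm.hip_excess_mortality_rr - 1.0),
        prod_loss_by_cycle=prod_loss,
        courses=tuple(courses),
        visit_cost=params.costs.physician_visit_cost,
        dxa_cost=params.costs.dxa_cost,
    )


def _treatment_timeline(
    c: _Compiled, u_disc: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic treatment timeline given the persistence draws.

    Returns per-cycle arrays: effective relative-risk multipliers
    (ncycles, 4), drug charges, and fixed formal costs (physician
    visits, DXA scans) charged only while persisting.
    """
    n = c.ncycles
    rr = np.ones((n, 4))
    drug_cost = np.zeros(n)
    fixed = np.zeros(n)
    offsets: List[Tuple[np.ndarray, int, float]] = []

    cursor = 0
    for ci, course in enumerate(c.courses):
        months = adh.sample_discontinuation(
            course.schedule, course.duration, u_disc[ci])
        years_done = adh.years_fully_persisted(months, course.duration)
        for y in range(1, years_done + 1):
            t = cursor + y - 1
            if t >= n:
                break
            rr[t] = np.minimum(rr[t], course.rr_by_year[y])
            drug_cost[t] += course.annual_cost * course.adherence_by_year[y]
            fixed[t] += course.visits_per_year * c.visit_cost
            if y in course.dxa_years:
                fixed[t] += c.dxa_cost
        if months is not None:
            # discontinued during year years_done + 1 (no efficacy, no
            # visit/DXA in that partial year)
            yd = years_done + 1
            t = cursor + yd - 1
            if t < n and yd <= course.duration:
                if yd == 1:
                    # 3-month minimum fill for first-year discontinuers
                    drug_cost[t] += course.annual_cost * 0.25
                else:
                    frac = months / 12.0 - (yd - 1)
                    drug_cost[t] += (course.annual_cost
                                     * course.adherence_by_year[yd] * frac)
            washout = adh.effective_washout_years(
                course.washout, years_done, course.duration)
            rr_stop = (course.rr_by_year[years_done]
                       if years_done >= 1 else np.ones(4))
            offsets.append((rr_stop, cursor + years_done, washout))
            break  # discontinuers do not begin the next course
        # full course completed: offset from the final treatment year
        offsets.append((course.rr_by_year[course.duration],
                        cursor + course.duration, course.washout))
        cursor += course.duration

    for rr_stop, stop, washout in offsets:
        if washout <= 0:
            continue
        for t in range(max(stop, 0), n):
            since = (t - stop) + 0.5  # mid-cycle of the post-stop year
            if since >= washout:
                break
            o = rr_stop + (1.0 - rr_stop) * (since / washout)
            rr[t] = np.minimum(rr[t], o)
    return rr, drug_cost, fixed


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class CycleRecord:
    cycle: int
    age: int
    event: Optional[FractureKind]
    died: bool
    components: Dict[str, float]  # undiscounted cost components
    utility: float  # undiscounted utility accrued
    discount_factor: float


@dataclass
class Trajectory:
    """Per-cycle record of one simulated woman plus discounted totals."""

    start_age: int
    records: List[CycleRecord]
    cost_formal: float  # discounted
    cost_nonhealth: float  # discounted
    qaly: float  # discounted
    fractures: Dict[FractureKind, int]
    died: bool

    def total_cost(self, perspective: Perspective) -> float:
        if perspective == Perspective.SOCIETAL:
            return self.cost_formal + self.cost_nonhealth
        return self.cost_formal


def _simulate_one(
    c: _Compiled,
    rng: np.random.Generator,
    collect: bool,
) -> Tuple[float, float, float, np.ndarray, bool, Optional[List[CycleRecord]]]:
    """Run one individual; returns (formal, nonhealth, qaly, fracture
    counts per type, died, records)."""
    u_disc = rng.random(_MAX_COURSES)
    u = rng.random((c.ncycles, 4))
    rr_mult, drug_cost, fixed_formal = _treatment_timeline(c, u_disc)

    frac_counts = np.zeros(4, dtype=np.int64)
    has_history = [False, False, False, False]
    hip_count = 0
    post_hip = False
    died = False
    cost_formal = 0.0
    cost_nonhealth = 0.0
    qaly = 0.0
    records: Optional[List[CycleRecord]] = [] if collect else None

    for t in range(c.ncycles):
        age = c.start_age + t
        q = c.q[t] * (c.excess_factor if post_hip else 1.0)
        if u[t, 0] < min(1.0, q):
            died = True
            if collect:
                records.append(CycleRecord(
                    cycle=t, age=age, event=None, died=True,
                    components={}, utility=0.0,
                    discount_factor=float(c.disc[t])))
            break

        p = c.base_p[t] * rr_mult[t]
        if hip_count >= 2:
            p[_HIP] = 0.0
        np.clip(p, 0.0, 1.0, out=p)
        event_idx: Optional[int] = None
        any_p = 1.0 - np.prod(1.0 - p)
        if any_p > 0.0 and u[t, 1] < any_p:
            cum = np.cumsum(p)
            event_idx = int(np.searchsorted(cum / cum[-1], u[t, 2],
                                            side="right"))

        components: Dict[str, float] = {}
        formal = drug_cost[t] + fixed_formal[t]
        nonhealth = 0.0
        if collect:
            if drug_cost[t]:
                components["drug"] = float(drug_cost[t])
            if fixed_formal[t]:
                components["physician_visits"] = float(fixed_formal[t])
        if post_hip:
            nonhealth += c.steady_ltc
            if collect:
                components["ltc_steady"] = c.steady_ltc
        if event_idx is not None:
            frac_counts[event_idx] += 1
            formal += c.frac_cost[event_idx]
            if collect:
                components["fracture_treatment"] = float(c.frac_cost[event_idx])
            if event_idx == _HIP:
                hip_count += 1
                if u[t, 3] < c.ltc_stay_fraction:
                    nonhealth += c.acute_ltc
                    if collect:
                        components["ltc_acute"] = c.acute_ltc
                loss = c.prod_loss_by_cycle[t]
                if loss:
                    nonhealth += loss
                    if collect:
                        components["productivity"] = float(loss)

        utility = c.baseline_u[t]
        for j in range(4):
            if has_history[j] and j != event_idx:
                utility *= c.subseq_mult[j]
        if event_idx is not None:
            utility *= c.first_mult[event_idx]

        d = c.disc[t]
        cost_formal += formal * d
        cost_nonhealth += nonhealth * d
        qaly += utility * d

        if event_idx is not None:
            has_history[event_idx] = True
            if event_idx == _HIP:
                post_hip = True
        if collect:
            records.append(CycleRecord(
                cycle=t, age=age,
                event=ALL_FRACTURES[event_idx] if event_idx is not None else None,
                died=False, components=components, utility=float(utility),
                discount_factor=float(d)))

    return cost_formal, cost_nonhealth, qaly, frac_counts, died, records


def _individual_seed(master_seed: int, stream: Tuple[int, ...],
                     i: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=tuple(stream) + (i,))


def simulate_individual(params: ParameterSet, scenario: ScenarioConfig,
                        seed: int | np.random.SeedSequence) -> Trajectory:
    """Simulate one woman and return her full cycle-by-cycle trajectory.

    Deterministic given the seed: the same seed reproduces the same
    trajectory bit for bit.
    """
    c = _compile(params, scenario)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    formal, nonhealth, qaly, counts, died, records = _simulate_one(
        c, rng, collect=True)
    return Trajectory(
        start_age=scenario.start_age,
        records=records or [],
        cost_formal=formal,
        cost_nonhealth=nonhealth,
        qaly=qaly,
        fractures={k: int(counts[j]) for k, j in _KIND_INDEX.items()},
        died=died,
    )


@dataclass
class CohortResult:
    """Monte-Carlo outcome of one strategy run over a cohort."""

    strategy: Strategy
    n: int
    cost_societal: np.ndarray
    cost_health_care: np.ndarray
    qaly: np.ndarray
    fracture_counts: np.ndarray  # (n, 4)
    died: np.ndarray  # (n,) bool

    def mean_cost(self, perspective: Perspective) -> float:
        return float(self._costs(perspective).mean())

    def se_cost(self, perspective: Perspective) -> float:
        a = self._costs(perspective)
        return float(a.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 else 0.0

    @property
    def mean_qaly(self) -> float:
        return float(self.qaly.mean())

    @property
    def se_qaly(self) -> float:
        return (float(self.qaly.std(ddof=1) / np.sqrt(self.n))
                if self.n > 1 else 0.0)

    def _costs(self, perspective: Perspective) -> np.ndarray:
        if perspective == Perspective.SOCIETAL:
            return self.cost_societal
        if perspective == Perspective.HEALTH_CARE_SECTOR:
            return self.cost_health_care
        raise ValueError(f"unknown perspective {perspective!r}")

    def lifetime_fracture_risk(self, kind: FractureKind) -> float:
        """Fraction of the cohort with at least one fracture of this type."""
        return float((self.fracture_counts[:, _KIND_INDEX[kind]] > 0).mean())

    @property
    def fraction_dead(self) -> float:
        return float(self.died.mean())

    def strategy_result(self, perspective: Perspective) -> econ.StrategyResult:
        return econ.StrategyResult(
            strategy=self.strategy.value,
            perspective=perspective,
            mean_cost=self.mean_cost(perspective),
            mean_qaly=self.mean_qaly,
            se_cost=self.se_cost(perspective),
            se_qaly=self.se_qaly,
            n=self.n,
        )


def run_cohort(
    params: ParameterSet,
    scenario: ScenarioConfig,
    stream: Tuple[int, ...] = (STREAM_BASE_CASE,),
) -> CohortResult:
    """Simulate ``scenario.n_individuals`` women one at a time.

    Per-individual seeds fan out from the master seed through the named
    substream; with ``common_random_numbers`` (the default) the i-th
    individual receives the same seed in every strategy, pairing the
    Monte-Carlo noise across strategies.
    """
    c = _compile(params, scenario)
    n = scenario.n_individuals
    if scenario.common_random_numbers:
        key = tuple(stream)
    else:
        key = tuple(stream) + (list(Strategy).index(scenario.strategy) + 1,)

    cost_soc = np.empty(n)
    cost_hcs = np.empty(n)
    qalys = np.empty(n)
    counts = np.empty((n, 4), dtype=np.int64)
    died = np.empty(n, dtype=bool)
    for i in range(n):
        rng = np.random.default_rng(
            _individual_seed(scenario.master_seed, key, i))
        formal, nonhealth, qaly, fc, d, _ = _simulate_one(c, rng, collect=False)
        cost_hcs[i] = formal
        cost_soc[i] = formal + nonhealth
        qalys[i] = qaly
        counts[i] = fc
        died[i] = d
    return CohortResult(
        strategy=scenario.strategy,
        n=n,
        cost_societal=cost_soc,
        cost_health_care=cost_hcs,
        qaly=qalys,
        fracture_counts=counts,
        died=died,
    )


def run_strategy_pair(
    params: ParameterSet,
    scenario: ScenarioConfig,
    intervention: Strategy = Strategy.SEQUENTIAL,
    comparator: Strategy = Strategy.ALENDRONATE_ALONE,
    stream: Tuple[int, ...] = (STREAM_BASE_CASE,),
) -> Tuple[CohortResult, CohortResult]:
    """Run intervention and comparator with paired seeds (when common
    random numbers are enabled)."""
    res = []
    for strat in (intervention, comparator):
        sc = scenario.model_copy(update={"strategy": strat})
        res.append(run_cohort(params, sc, stream=stream))
    return res[0], res[1]
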