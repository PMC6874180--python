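"""One-way, threshold, and probabilistic sensitivity analyses.

One-way analysis substitutes a single scalar in the parameter set and
re-runs both strategies with paired seeds.  The teriparatide-cost
threshold analysis walks the generic/biosimilar discount grid (30% to
95% in 5% steps) and reports the smallest discount at which the ICER
falls below a willingness-to-pay threshold.  Probabilistic sensitivity
analysis is two-level: an outer loop draws one value per uncertain
parameter from its distribution, an inner loop runs the
microsimulation for both strategies with paired seeds and records the
incremental (cost, QALY) pair; cost-effectiveness acceptability curves
summarise the fraction of outer draws with non-negative net monetary
benefit at each willingness-to-pay value.

Distribution fitting: triangular uses the printed range as its
support with the base value as mode; beta is fitted on the printed
range as support with mean at the base value and the range read as a
central ~95% interval; log-normal matches its median to the base value
with the range as a 95% interval; gamma matches its mean with the
range as a 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import economics as econ
from . import pricing
from .engine import STREAM_PSA, run_strategy_pair
from .parameters import (
    DistributionSpec,
    Drug,
    ParameterSet,
    Perspective,
    ScenarioConfig,
    Strategy,
    set_by_path,
    set_many_by_path,
)

_Z95 = 2 * 1.959963984540054  # width of a central 95% normal interval in sd units


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value for an uncertain parameter.

    point_mass returns the base value; triangular samples on
    [low, high] with mode at base; beta samples on [low, high] with
    mean at base; log-normal has median base; gamma has mean base.
    """
    if spec.kind == "point_mass":
        return spec.base
    if spec.kind == "triangular":
        if spec.low == spec.high:
            return spec.base
        return float(rng.triangular(spec.low, spec.base, spec.high))
    if spec.kind == "beta":
        width = spec.high - spec.low
        if width <= 0:
            return spec.base
        mean = (spec.base - spec.low) / width
        if not (0 < mean < 1):
            raise ValueError(
                f"beta spec requires low < base < high, got {spec}")
        sd = 1.0 / _Z95  # range read as a central 95% interval of the support
        var = min(sd * sd, 0.999 * mean * (1 - mean))
        kappa = mean * (1 - mean) / var - 1.0
        a, b = mean * kappa, (1 - mean) * kappa
        return float(spec.low + width * rng.beta(a, b))
    if spec.kind == "log_normal":
        if spec.base <= 0 or spec.low <= 0:
            raise ValueError("log-normal spec requires positive base and low")
        mu = math.log(spec.base)
        sigma = (math.log(spec.high) - math.log(spec.low)) / _Z95
        return float(rng.lognormal(mu, sigma))
    if spec.kind == "gamma":
        if spec.base <= 0:
            raise ValueError("gamma spec requires positive base")
        sd = (spec.high - spec.low) / _Z95
        if sd <= 0:
            return spec.base
        shape = (spec.base / sd) ** 2
        scale = sd * sd / spec.base
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown distribution kind {spec.kind!r}")


def _paired_icer(
    params: ParameterSet,
    scenario: ScenarioConfig,
    perspective: Perspective = Perspective.SOCIETAL,
    stream: Tuple[int, ...] = (0,),
) -> econ.ICERResult:
    inter, comp = run_strategy_pair(params, scenario, stream=stream)
    return econ.compute_icer(
        inter.strategy_result(perspective), comp.strategy_result(perspective))


def run_owsa(
    params: ParameterSet,
    scenario: ScenarioConfig,
    param_path: str,
    values: Sequence[float],
    perspective: Perspective = Perspective.SOCIETAL,
) -> List[econ.ICERResult]:
    """One-way deterministic sensitivity analysis.

    For each value, rebuild the parameter set with the single scalar at
    ``param_path`` replaced, run both strategies with paired seeds, and
    return the ICERs in input order.
    """
    out: List[econ.ICERResult] = []
    for v in values:
        varied = set_by_path(params, param_path, v)
        out.append(_paired_icer(varied, scenario, perspective))
    return out


@dataclass
class ThresholdResult:
    """Outcome of the teriparatide-discount threshold search."""

    wtp: float
    generic_share: float
    discount: float | None  # smallest qualifying grid discount, or None
    annual_costs: Dict[float, float]  # discount -> blended annual cost
    icers: Dict[float, econ.ICERResult]


def threshold_discount(
    params: ParameterSet,
    scenario: ScenarioConfig,
    wtp: float,
    generic_share: float = 0.9,
    discounts: Sequence[float] = pricing.DEFAULT_DISCOUNT_GRID,
    perspective: Perspective = Perspective.SOCIETAL,
) -> ThresholdResult:
    """Smallest generic/biosimilar teriparatide discount on the grid at
    which the sequential strategy becomes cost-effective at ``wtp``."""
    brand = pricing.brand_annual_cost(params.pricing[Drug.TERIPARATIDE])
    annual_costs: Dict[float, float] = {}
    icers: Dict[float, econ.ICERResult] = {}
    found: float | None = None
    for d in discounts:
        annual = pricing.blended_annual_cost(
            brand, pricing.discounted_generic_cost(brand, d), generic_share)
        annual_costs[d] = annual
        varied = set_by_path(
            params, "costs.annual_drug_cost.teriparatide", annual)
        res = _paired_icer(varied, scenario, perspective)
        icers[d] = res
        if found is None and res.cost_effective_at(wtp):
            found = d
    return ThresholdResult(
        wtp=wtp, generic_share=generic_share, discount=found,
        annual_costs=annual_costs, icers=icers)


@dataclass
class PSAResult:
    """Per-simulation incremental (cost, QALY) pairs from the outer loop."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_simulations: int
    n_trials: int
    seed: int
    perspective: Perspective

    def __post_init__(self) -> None:
        if len(self.delta_cost) != self.n_simulations:
            raise ValueError("delta_cost length must equal n_simulations")
        if not (np.all(np.isfinite(self.delta_cost))
                and np.all(np.isfinite(self.delta_qaly))):
            raise ValueError("PSA results must be finite")


def run_psa(
    params: ParameterSet,
    scenario: ScenarioConfig,
    n_simulations: int = 1000,
    n_trials: int = 10_000,
    seed: int | None = None,
    perspective: Perspective = Perspective.SOCIETAL,
) -> PSAResult:
    """Two-level probabilistic sensitivity analysis.

    The outer loop samples every parameter carrying a distribution in
    ``params.uncertainty``; the inner loop runs ``n_trials``
    microsimulated women per strategy with paired seeds.  Reproducible
    given the seed.
    """
    seed = scenario.master_seed if seed is None else seed
    outer_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(STREAM_PSA, 0)))
    dcs = np.empty(n_simulations)
    des = np.empty(n_simulations)
    paths = sorted(params.uncertainty)
    for s in range(n_simulations):
        draws = {
            path: sample_parameter(params.uncertainty[path], outer_rng)
            for path in paths
        }
        # independent draws may invert the 12m >= 24m ordering; clamp the
        # 24-month value so the schedule stays monotone
        for drug in Drug:
            for stem in ("persistence", "adherence"):
                k12 = f"adherence.{drug.value}.{stem}_12m"
                k24 = f"adherence.{drug.value}.{stem}_24m"
                if k12 in draws and k24 in draws:
                    draws[k24] = min(draws[k24], draws[k12])
        # unbounded (gamma) draws are floored at the structural bound for
        # risk elevations, which must stay multiplicative (>= 1)
        for path in paths:
            if path.startswith("risks.rr_"):
                draws[path] = max(1.0, draws[path])
        varied = set_many_by_path(params, draws)
        # inner trials reuse the same paired seeds in every outer
        # simulation: variation across simulations comes from the
        # parameter draws alone
        inner = scenario.model_copy(
            update={"n_individuals": n_trials, "master_seed": seed})
        inter, comp = run_strategy_pair(varied, inner, stream=(STREAM_PSA, 1))
        dcs[s] = (inter.mean_cost(perspective) - comp.mean_cost(perspective))
        des[s] = inter.mean_qaly - comp.mean_qaly
    return PSAResult(
        delta_cost=dcs, delta_qaly=des, n_simulations=n_simulations,
        n_trials=n_trials, seed=seed, perspective=perspective)


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> List[Tuple[float, float]]:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value, the fraction of outer simulations
    with non-negative net monetary benefit (wtp * ΔE - ΔC >= 0).
    """
    if psa.n_simulations == 0:
        raise ValueError("empty PSA result")
    out = []
    for wtp in wtp_grid:
        nmb = wtp * psa.delta_qaly - psa.delta_cost
        out.append((float(wtp), float((nmb >= 0).mean())))
    return out
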