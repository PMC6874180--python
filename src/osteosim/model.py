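"""Model/Results facade over the microsimulation pipeline.

:class:`CostEffectivenessModel` bundles a parameter set with a cohort
scenario; :meth:`~CostEffectivenessModel.fit` runs the paired
microsimulation and returns a :class:`CostEffectivenessResults` object
carrying per-strategy discounted mean costs and QALYs with their
Monte-Carlo standard errors, ICERs under both perspectives, and a
``summary()`` table.  Sensitivity analyses hang off the fitted results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import pandas as pd

from . import economics as econ
from . import sensitivity as sens
from .engine import CohortResult, run_strategy_pair
from .parameters import (
    ParameterSet,
    Perspective,
    ScenarioConfig,
    Strategy,
    default_parameter_set,
    load_parameter_set,
)


class CostEffectivenessModel:
    """Sequential teriparatide/alendronate vs alendronate alone.

    Parameters
    ----------
    params :
        Validated model inputs; defaults to :func:`default_parameter_set`.
    start_age :
        Cohort age at therapy initiation (65, 70, 75, or 80 in the
        reference analysis).
    discount_rate :
        Annual discount rate for costs and QALYs.
    common_random_numbers :
        Pair per-individual seeds across strategies (variance reduction
        for the incremental estimates).
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        start_age: int = 65,
        discount_rate: float = 0.03,
        intervention: Strategy = Strategy.SEQUENTIAL,
        comparator: Strategy = Strategy.ALENDRONATE_ALONE,
        common_random_numbers: bool = True,
    ) -> None:
        self.params = params if params is not None else default_parameter_set()
        self.start_age = start_age
        self.discount_rate = discount_rate
        self.intervention = intervention
        self.comparator = comparator
        self.common_random_numbers = common_random_numbers

    @classmethod
    def from_config(cls, config_path, tables_dir, **kwargs
                    ) -> "CostEffectivenessModel":
        return cls(params=load_parameter_set(config_path, tables_dir), **kwargs)

    def scenario(self, n_individuals: int, seed: int,
                 strategy: Strategy | None = None) -> ScenarioConfig:
        return ScenarioConfig(
            start_age=self.start_age,
            strategy=strategy or self.intervention,
            discount_rate=self.discount_rate,
            n_individuals=n_individuals,
            master_seed=seed,
            common_random_numbers=self.common_random_numbers,
        )

    def fit(self, n_individuals: int = 10_000, seed: int = 0
            ) -> "CostEffectivenessResults":
        """Run both strategies with paired seeds and summarise."""
        scenario = self.scenario(n_individuals, seed)
        inter, comp = run_strategy_pair(
            self.params, scenario,
            intervention=self.intervention, comparator=self.comparator)
        return CostEffectivenessResults(
            model=self, scenario=scenario,
            intervention=inter, comparator=comp)


@dataclass
class CostEffectivenessResults:
    """Fitted Monte-Carlo estimates for one cohort start age."""

    model: CostEffectivenessModel
    scenario: ScenarioConfig
    intervention: CohortResult
    comparator: CohortResult

    def strategy_result(self, strategy: Strategy,
                        perspective: Perspective) -> econ.StrategyResult:
        cohort = (self.intervention
                  if strategy == self.intervention.strategy else self.comparator)
        return cohort.strategy_result(perspective)

    def icer(self, perspective: Perspective = Perspective.SOCIETAL
             ) -> econ.ICERResult:
        return econ.compute_icer(
            self.intervention.strategy_result(perspective),
            self.comparator.strategy_result(perspective))

    def summary(self) -> pd.DataFrame:
        """Cost/QALY/ICER table in the conventional base-case layout
        (dollars to the nearest dollar, QALYs to 2 decimals, ICERs to
        the nearest $100; the comparator is the reference row)."""
        rows = []
        for persp in Perspective:
            for cohort, role in ((self.comparator, "reference"),
                                 (self.intervention, "intervention")):
                sr = cohort.strategy_result(persp)
                if role == "reference":
                    icer_txt = "Reference"
                else:
                    res = self.icer(persp)
                    icer_txt = (res.label if res.icer is None
                                else f"{econ.round_icer(res.icer):,.0f}")
                rows.append({
                    "perspective": persp.value,
                    "strategy": sr.strategy,
                    "cost": round(sr.mean_cost),
                    "qaly": round(sr.mean_qaly, 2),
                    "icer": icer_txt,
                    "se_cost": sr.se_cost,
                    "se_qaly": sr.se_qaly,
                    "n": sr.n,
                })
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    # sensitivity analyses (delegating to the sensitivity module with the
    # model's parameter set and scenario)

    def run_owsa(self, param_path: str, values: Sequence[float],
                 perspective: Perspective = Perspective.SOCIETAL):
        return sens.run_owsa(self.model.params, self.scenario,
                             param_path, values, perspective)

    def threshold_discount(self, wtp: float, generic_share: float = 0.9,
                           **kwargs) -> sens.ThresholdResult:
        return sens.threshold_discount(
            self.model.params, self.scenario, wtp,
            generic_share=generic_share, **kwargs)

    def run_psa(self, n_simulations: int, n_trials: int,
                seed: int | None = None,
                perspective: Perspective = Perspective.SOCIETAL
                ) -> sens.PSAResult:
        return sens.run_psa(self.model.params, self.scenario,
                            n_simulations=n_simulations, n_trials=n_trials,
                            seed=seed, perspective=perspective)
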