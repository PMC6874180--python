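"""Medication cost model.

Annual drug costs are built from list-price primitives: a unit (fill)
price, the number of fills per year (52 weekly tablets for alendronate,
13 × 28-day supplies for teriparatide), and the fraction of the list
price actually paid.  Brand and generic/biosimilar annual costs are
then blended by the market share of the generic product.  All
arithmetic keeps full precision internally; only reported figures are
rounded to the nearest dollar.

The threshold analysis varies the generic/biosimilar discount in 5%
steps and the generic market share over {0.9, 0.75, 0.6}, producing the
annual-cost grid used for the cost-effectiveness threshold search.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .parameters import PricingAssumption


def annual_drug_cost(unit_price: float, fills_per_year: float,
                     price_factor: float) -> float:
    """Annual cost = unit price x fills/year x fraction of list price paid."""
    if unit_price < 0 or fills_per_year < 0 or price_factor < 0:
        raise ValueError("pricing inputs must be non-negative")
    return unit_price * fills_per_year * price_factor


def discounted_generic_cost(brand_annual: float, generic_discount: float) -> float:
    """Generic/biosimilar annual cost as a discount off the brand annual cost."""
    if not (0.0 <= generic_discount <= 1.0):
        raise ValueError("generic_discount must be in [0, 1]")
    if brand_annual < 0:
        raise ValueError("brand_annual must be non-negative")
    return brand_annual * (1.0 - generic_discount)


def blended_annual_cost(brand_annual: float, generic_annual: float,
                        generic_share: float) -> float:
    """Convex mix of generic and brand annual costs by generic market share."""
    if not (0.0 <= generic_share <= 1.0):
        raise ValueError("generic_share must be in [0, 1]")
    return generic_annual * generic_share + brand_annual * (1.0 - generic_share)


def brand_annual_cost(assumption: PricingAssumption) -> float:
    return annual_drug_cost(
        assumption.brand_unit_price,
        assumption.fills_per_year,
        assumption.brand_price_factor,
    )


def generic_annual_cost(assumption: PricingAssumption) -> float:
    if assumption.generic_unit_price is not None:
        return annual_drug_cost(
            assumption.generic_unit_price,
            assumption.fills_per_year,
            assumption.generic_price_factor or 0.0,
        )
    return discounted_generic_cost(
        brand_annual_cost(assumption), assumption.generic_discount or 0.0
    )


def blended_annual_cost_from_assumption(assumption: PricingAssumption) -> float:
    """Full-precision blended annual cost implied by a pricing assumption."""
    return blended_annual_cost(
        brand_annual_cost(assumption),
        generic_annual_cost(assumption),
        assumption.generic_share,
    )


def teriparatide_cost_grid(
    discounts: Sequence[float],
    shares: Sequence[float],
    brand_annual: float,
) -> pd.DataFrame:
    """Blended annual cost over a (discount x generic share) grid.

    Rows are generic/biosimilar discounts off brand, columns are
    generic market shares.  Each cell is
    ``blended_annual_cost(brand, brand*(1-d), s)`` at full precision;
    the grid is non-increasing along both axes.
    """
    rows = {}
    for d in discounts:
        generic = discounted_generic_cost(brand_annual, d)
        rows[d] = {s: blended_annual_cost(brand_annual, generic, s) for s in shares}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "discount"
    df.columns.name = "generic_share"
    return df


DEFAULT_DISCOUNT_GRID: tuple = tuple(round(0.30 + 0.05 * i, 2) for i in range(14))
DEFAULT_SHARE_GRID: tuple = (0.9, 0.75, 0.6)


def cycle_drug_charge(
    annual_cost: float,
    on_treatment: bool,
    adherence: float,
    discontinued_within_first_year: bool,
    fraction_of_year_on_drug: float = 1.0,
) -> float:
    """Drug cost charged for one annual cycle.

    A persisting individual pays the annual cost prorated by her
    adherence.  A first-year discontinuer pays for a single 3-month
    supply (one quarter of the annual cost), once, in place of the
    adherence-prorated charge.  A later-year discontinuer pays the
    adherence-prorated charge further prorated by the fraction of the
    year she remained on drug.  Individuals not on treatment pay 0.
    """
    if not (0.0 <= adherence <= 1.0):
        raise ValueError("adherence must be in [0, 1]")
    if discontinued_within_first_year:
        return annual_cost * 0.25
    if not on_treatment:
        return 0.0
    return annual_cost * adherence * fraction_of_year_on_drug


def round_dollar(x: float) -> int:
    """Round a reported dollar figure to the nearest dollar."""
    import math

    return int(math.floor(x + 0.5))
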