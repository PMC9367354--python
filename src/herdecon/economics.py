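"""Income/cost accounting per cow-year.

Converts annual technical results into the standard five-line income /
seven-line cost statement and the contribution margin (total income
minus variable costs). All items are EUR per cow-year; dead-stock
disposal fees are netted into the corresponding income lines so the
line structure of the published statement is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config_io import TREATED_DISEASES, PriceTable
from .simulator import AnnualTechnicalResult

INCOME_ITEMS = ("milk", "slaughter_cows", "calves", "slaughter_heifers", "heifers_live")
COST_ITEMS = (
    "feed_cows",
    "feed_heifers",
    "insemination_cows",
    "insemination_heifers",
    "veterinary_cows",
    "other_cows",
    "other_heifers",
)


@dataclass(frozen=True)
class EconomicResult:
    """Annual income/cost statement, EUR per cow-year.

    The totals are stored, not recomputed, and are exact sums of the
    item maps by construction (enforced at init).
    """

    income: Mapping[str, float]
    costs: Mapping[str, float]
    total_income: float = field(default=None)  # type: ignore[assignment]
    variable_costs: float = field(default=None)  # type: ignore[assignment]
    contribution_margin: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        missing = [k for k in INCOME_ITEMS if k not in self.income]
        missing += [k for k in COST_ITEMS if k not in self.costs]
        if missing:
            raise ValueError(f"statement is missing items: {missing}")
        object.__setattr__(self, "income", {k: float(self.income[k]) for k in INCOME_ITEMS})
        object.__setattr__(self, "costs", {k: float(self.costs[k]) for k in COST_ITEMS})
        object.__setattr__(self, "total_income", sum(self.income.values()))
        object.__setattr__(self, "variable_costs", sum(self.costs.values()))
        object.__setattr__(
            self, "contribution_margin", self.total_income - self.variable_costs
        )

    @classmethod
    def from_line_items(
        cls, income: Mapping[str, float], costs: Mapping[str, float]
    ) -> "EconomicResult":
        """Build a statement directly from given line items (e.g. a
        published table) — totals and margin follow by the accounting
        identity."""
        return cls(income=dict(income), costs=dict(costs))


def compute_annual_economics(
    tech: AnnualTechnicalResult, prices: PriceTable
) -> EconomicResult:
    """Price one technical record into EUR per cow-year."""
    cy = tech.cow_years
    if cy <= 0:
        raise ValueError("cow_years must be > 0 to express items per cow-year")

    income = {
        "milk": tech.kg_ecm_delivered * prices.milk_price_per_kg_ecm / cy,
        "slaughter_cows": (
            tech.cows_slaughtered_weight_kg * prices.slaughter_price_per_kg_live
            - tech.cow_deaths * prices.dead_cow_disposal
        )
        / cy,
        "calves": (
            tech.live_calves_male * prices.bull_calf_price
            - (tech.stillbirths + tech.calf_deaths_early) * prices.dead_calf_disposal
        )
        / cy,
        "slaughter_heifers": (
            tech.heifers_sold_open * prices.open_heifer_price
            - tech.calf_deaths_late * prices.dead_heifer_disposal
        )
        / cy,
        "heifers_live": tech.heifers_sold_pregnant * prices.pregnant_heifer_price / cy,
    }
    veterinary = sum(
        tech.disease_cases.get(d, 0.0) * prices.treatment_cost[d] for d in TREATED_DISEASES
    )
    costs = {
        "feed_cows": (
            tech.feed_sfu_cows_concentrate * prices.cow_concentrate_per_sfu
            + tech.feed_sfu_cows_roughage * prices.cow_roughage_per_sfu
        )
        / cy,
        "feed_heifers": (
            tech.feed_sfu_heifers_concentrate * prices.heifer_concentrate_per_sfu
            + tech.feed_sfu_heifers_roughage * prices.heifer_roughage_per_sfu
            + tech.milk_powder_kg * prices.milk_powder_per_kg
        )
        / cy,
        "insemination_cows": tech.inseminations_cows * prices.semen_cost / cy,
        "insemination_heifers": tech.inseminations_heifers * prices.semen_cost / cy,
        "veterinary_cows": veterinary / cy,
        "other_cows": prices.other_costs_per_cow_year,
        "other_heifers": prices.other_costs_per_heifer_year * tech.heifer_years / cy,
    }
    return EconomicResult(income=income, costs=costs)


def decompose_scenario_delta(
    high: Sequence[EconomicResult], low: Sequence[EconomicResult]
) -> dict[str, float]:
    """Mean(high) - mean(low) per statement item plus the margin.

    Item deltas sum exactly (income positive, costs negative) to the
    margin delta.
    """
    if not high or not low:
        raise ValueError("both scenario sets must be non-empty")

    def mean(results, getter):
        return sum(getter(r) for r in results) / len(results)

    delta: dict[str, float] = {}
    for item in INCOME_ITEMS:
        delta[f"income_{item}"] = mean(high, lambda r: r.income[item]) - mean(
            low, lambda r: r.income[item]
        )
    for item in COST_ITEMS:
        delta[f"cost_{item}"] = mean(high, lambda r: r.costs[item]) - mean(
            low, lambda r: r.costs[item]
        )
    delta["total_income"] = sum(delta[f"income_{i}"] for i in INCOME_ITEMS)
    delta["variable_costs"] = sum(delta[f"cost_{i}"] for i in COST_ITEMS)
    delta["contribution_margin"] = delta["total_income"] - delta["variable_costs"]
    return delta
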