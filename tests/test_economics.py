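import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdecon.economics import (
    COST_ITEMS,
    INCOME_ITEMS,
    EconomicResult,
    compute_annual_economics,
    decompose_scenario_delta,
)
from herdecon.simulator import annual_aggregate, combine_annual_results

# Published annual statements (EUR per cow-year) used as accounting
# fixtures: five income lines and seven cost lines per breed.
PUBLISHED_STATEMENTS = {
    "LBW": ([2110, 143, 100, 16, 63], [1027, 247, 35, 13, 105, 202, 47], 2432, 1676, 756),
    "LR": ([2148, 136, 76, 12, 75], [1040, 238, 13, 5, 109, 202, 46], 2447, 1653, 794),
    "LROG": ([1675, 140, 77, 11, 73], [898, 229, 12, 5, 111, 202, 45], 1976, 1502, 474),
}


def _statement(income_values, cost_values):
    return EconomicResult.from_line_items(
        dict(zip(INCOME_ITEMS, income_values)), dict(zip(COST_ITEMS, cost_values))
    )


class TestAccountingIdentity:
    @pytest.mark.parametrize("breed", ["LBW", "LR", "LROG"])
    def test_published_statements(self, breed):
        income, costs, total, variable, margin = PUBLISHED_STATEMENTS[breed]
        result = _statement(income, costs)
        assert result.total_income == total
        assert result.variable_costs == variable
        assert result.contribution_margin == margin

    def test_zero_statement(self):
        result = _statement([0] * 5, [0] * 7)
        assert result.total_income == 0
        assert result.contribution_margin == 0

    @given(
        income=st.lists(st.floats(0, 5000, allow_nan=False), min_size=5, max_size=5),
        costs=st.lists(st.floats(0, 5000, allow_nan=False), min_size=7, max_size=7),
    )
    @settings(max_examples=50, deadline=None)
    def test_identity_exact_property(self, income, costs):
        result = _statement(income, costs)
        assert result.total_income == pytest.approx(sum(income), rel=1e-9, abs=1e-9)
        assert result.variable_costs == pytest.approx(sum(costs), rel=1e-9, abs=1e-9)
        assert result.contribution_margin == pytest.approx(
            result.total_income - result.variable_costs, rel=1e-9, abs=1e-9
        )

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            EconomicResult.from_line_items({"milk": 1.0}, {})


class TestComputeAnnualEconomics:
    def test_all_zero_technical_result(self, prices_lbw):
        tech = annual_aggregate({"cow_weeks": 52.0}, replicate_id=0, year_index=0)
        result = compute_annual_economics(tech, prices_lbw)
        assert result.total_income == 0
        assert result.costs["other_cows"] == prices_lbw.other_costs_per_cow_year
        assert result.contribution_margin == -prices_lbw.other_costs_per_cow_year

    def test_zero_cow_years_rejected(self, prices_lbw):
        tech = annual_aggregate({}, replicate_id=0, year_index=0)
        with pytest.raises(ValueError, match="cow_years"):
            compute_annual_economics(tech, prices_lbw)

    def test_line_pricing_arithmetic(self, prices_lbw, lbw):
        counts = {
            "cow_weeks": 100 * 52.0,
            "kg_ecm": 600_000.0,
            "cows_slaughtered": 10.0,
            "cow_deaths": 2.0,
            "live_calves_male": 40.0,
            "heifers_sold_pregnant": 5.0,
            "heifers_sold_open": 1.0,
            "inseminations_cows": 150.0,
            "disease_cases": {"mastitis": 20.0},
            "calvings": 80.0,
        }
        tech = annual_aggregate(counts, replicate_id=0, year_index=0, params=lbw)
        result = compute_annual_economics(tech, prices_lbw)
        assert result.income["milk"] == pytest.approx(600_000 * 0.29 / 100)
        assert result.income["slaughter_cows"] == pytest.approx((10 * 550 * 0.94 - 2 * 33) / 100)
        assert result.income["calves"] == pytest.approx(40 * 200 / 100)
        assert result.income["heifers_live"] == pytest.approx(5 * 1300 / 100)
        assert result.costs["insemination_cows"] == pytest.approx(150 * 20 / 100)
        assert result.costs["veterinary_cows"] == pytest.approx(20 * 89 / 100)

    def test_lameness_has_no_treatment_cost(self, prices_lbw):
        tech = annual_aggregate(
            {"cow_weeks": 52.0, "disease_cases": {"lameness": 5.0}},
            replicate_id=0,
            year_index=0,
        )
        assert compute_annual_economics(tech, prices_lbw).costs["veterinary_cows"] == 0

    def test_milk_price_monotonicity(self, lbw_small_run, prices_lbw):
        tech = combine_annual_results(lbw_small_run.replicate(0))
        low = compute_annual_economics(tech, prices_lbw)
        pricier = dataclasses.replace(prices_lbw, milk_price_per_kg_ecm=0.35)
        high = compute_annual_economics(tech, pricier)
        assert high.income["milk"] > low.income["milk"]
        assert high.contribution_margin > low.contribution_margin

    def test_simulated_statement_identity(self, lbw_small_run, prices_lbw):
        for rep in lbw_small_run:
            result = compute_annual_economics(combine_annual_results(rep), prices_lbw)
            assert result.contribution_margin == pytest.approx(
                result.total_income - result.variable_costs, rel=1e-12
            )


class TestBaselinePlausibility:
    def test_lrog_cow_feed_cost_is_lowest(self, lbw, lr, lrog, prices_lbw, prices_lr, prices_lrog):
        from herdecon.simulator import simulate_batch

        feed = {}
        for params, prices in ((lbw, prices_lbw), (lr, prices_lr), (lrog, prices_lrog)):
            out = simulate_batch(params, years=8, burn_in=3, seed=31, n_replicates=15)
            costs = [
                compute_annual_economics(combine_annual_results(r), prices).costs["feed_cows"]
                for r in out
            ]
            feed[params.breed_id] = float(np.mean(costs))
        assert feed["LROG"] < feed["LR"]
        assert feed["LROG"] < feed["LBW"]


class TestScenarioDelta:
    def test_identical_sets_give_zero(self, lbw_small_run, prices_lbw):
        econ = [
            compute_annual_economics(combine_annual_results(r), prices_lbw)
            for r in lbw_small_run
        ]
        delta = decompose_scenario_delta(econ, econ)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in delta.values())

    def test_single_pair_additivity(self):
        low = _statement([2100, 140, 100, 16, 63], [1027, 247, 35, 13, 105, 202, 47])
        high = _statement([2106, 140, 100, 16, 63], [1027, 247, 35, 13, 105, 202, 47])
        delta = decompose_scenario_delta([high], [low])
        assert delta["contribution_margin"] == pytest.approx(6.0)
        item_sum = sum(delta[f"income_{i}"] for i in INCOME_ITEMS) - sum(
            delta[f"cost_{i}"] for i in COST_ITEMS
        )
        assert item_sum == pytest.approx(delta["contribution_margin"])

    @given(
        shifts=st.lists(st.floats(-50, 50, allow_nan=False), min_size=12, max_size=12),
    )
    @settings(max_examples=30, deadline=None)
    def test_known_shift_recovery(self, shifts):
        # oracle: direct arithmetic on constructed inputs
        base_income = [2000.0, 150.0, 90.0, 20.0, 60.0]
        base_costs = [1000.0, 250.0, 30.0, 10.0, 100.0, 200.0, 50.0]
        low = _statement(base_income, base_costs)
        high = _statement(
            [b + s for b, s in zip(base_income, shifts[:5])],
            [b + s for b, s in zip(base_costs, shifts[5:])],
        )
        delta = decompose_scenario_delta([high], [low])
        for item, shift in zip(INCOME_ITEMS, shifts[:5]):
            assert delta[f"income_{item}"] == pytest.approx(shift, abs=1e-9)
        for item, shift in zip(COST_ITEMS, shifts[5:]):
            assert delta[f"cost_{item}"] == pytest.approx(shift, abs=1e-9)
        expected_margin = sum(shifts[:5]) - sum(shifts[5:])
        assert delta["contribution_margin"] == pytest.approx(expected_margin, abs=1e-9)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            decompose_scenario_delta([], [])
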