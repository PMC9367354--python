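import dataclasses
import math

import numpy as np
import pytest

from herdecon.errors import SimulationError, ValidationError
from herdecon.simulator import (
    _WOOD_NORM,
    AnnualTechnicalResult,
    CowState,
    GESTATION_WEEKS,
    HerdState,
    WEEKS_PER_YEAR,
    annual_aggregate,
    combine_annual_results,
    compute_repro_calibration,
    lactation_yield,
    simulate_batch,
    simulate_herd,
    step_week,
    _wood_shape,
)


def _null_params(base, **overrides):
    """All hazards off: no diseases, no deaths, no breeding."""
    return dataclasses.replace(
        base,
        incidence_per_100cy={d: 0.0 for d in base.incidence_per_100cy},
        stillbirth_rate=0.0,
        early_calf_mortality=0.0,
        late_calf_mortality=0.0,
        cow_mortality=0.0,
        heat_obs_rate_cows=0.0,
        heat_obs_rate_heifers=0.0,
        oestrus_scale_cows=0.0,
        heifer_breeding_start_weeks=1e4,
        **overrides,
    )


class TestLactationYield:
    @pytest.mark.parametrize(
        "breed_fixture, cls, total",
        [
            ("lbw", "1", 6741),
            ("lbw", "2", 7648),
            ("lbw", "3+", 7526),
            ("lrog", "2", 5553),
            ("lr", "1", 6907),
        ],
    )
    def test_cumulative_305d_matches_calibration(self, request, breed_fixture, cls, total):
        # oracle: numeric integration of the curve on the weekly grid
        params = request.getfixturevalue(breed_fixture)
        weekly = [lactation_yield(cls, w, params) for w in range(1, 44)]
        cumulative = sum(weekly) + (4 / 7) * lactation_yield(cls, 44, params)
        assert cumulative == pytest.approx(total, rel=0.01)

    def test_zero_before_calving(self, lbw):
        assert lactation_yield("1", 0, lbw) == 0.0

    def test_unknown_parity_class(self, lbw):
        with pytest.raises(ValueError, match="parity class"):
            lactation_yield("4", 10, lbw)

    def test_negative_week(self, lbw):
        with pytest.raises(ValueError):
            lactation_yield("1", -1, lbw)

    def test_shape_is_unimodal_with_interior_peak(self):
        y = _wood_shape(np.arange(1, 100))
        peak = int(np.argmax(y))
        assert 2 <= peak <= 20
        assert np.all(np.diff(y[peak:]) <= 0)
        assert _WOOD_NORM > 0


class TestStepWeek:
    def test_null_hazards_yield_accrual_only(self, lbw):
        params = _null_params(lbw)
        st = HerdState(params, n_replicates=1)
        st.add_cow(CowState(animal_id=(0, 0), parity=2, week_in_milk=10, repro_status="open", weeks_pregnant=0))
        rng = np.random.default_rng(0)
        step_week(st, params, rng)
        assert st.acc["kg_ecm"][0] == pytest.approx(lactation_yield("2", 10, lbw), rel=1e-5)
        for key in ("calvings", "cow_deaths", "inseminations_cows", "stillbirths"):
            assert st.acc[key][0] == 0
        assert st.acc["disease_cases"].sum() == 0
        assert st.cow(0, 0).week_in_milk == 11  # clock advanced

    def test_forced_calving_at_term(self, lbw):
        params = _null_params(lbw)
        st = HerdState(params, n_replicates=1)
        st.add_cow(CowState(animal_id=(0, 0), parity=1, week_in_milk=50, repro_status="pregnant", weeks_pregnant=GESTATION_WEEKS))
        step_week(st, params, np.random.default_rng(1))
        cow = st.cow(0, 0)
        assert st.acc["calvings"][0] == 1
        assert cow.parity == 2
        assert cow.weeks_pregnant == 0

    def test_weekly_hazard_matches_binomial_oracle(self, lbw):
        # oracle: closed-form binomial moments on cow-weeks at risk
        params = _null_params(lbw)
        params = dataclasses.replace(
            params,
            incidence_per_100cy={**params.incidence_per_100cy, "mastitis": 26.0},
        )
        st = HerdState(params, n_replicates=200)
        for r in range(200):
            for s in range(30):
                st.add_cow(CowState(animal_id=(r, s), parity=1, week_in_milk=1, repro_status="open", weeks_pregnant=0))
        rng = np.random.default_rng(3)
        h = st.derived.hazard[st.derived.hazard > 0][0]
        expected_onsets = 0.0
        for _ in range(8):
            at_risk = (st.c_active & (st.c_dis[4] == 0)).sum()
            expected_onsets += h * at_risk
            step_week(st, params, rng)
        observed = st.acc["disease_cases"][:, 4].sum()
        se = math.sqrt(expected_onsets)
        assert abs(observed - expected_onsets) < 3 * se


class TestSimulateHerd:
    def test_record_count(self, lbw_small_run):
        assert lbw_small_run.n_replicates == 20
        assert all(len(rep) == 5 for rep in lbw_small_run)

    def test_years_must_exceed_burn_in(self, lbw):
        with pytest.raises(ValueError):
            simulate_herd(lbw, years=5, burn_in=5, seed=0)

    def test_seed_determinism(self, lbw):
        a = simulate_herd(lbw, years=4, burn_in=2, seed=9)
        b = simulate_herd(lbw, years=4, burn_in=2, seed=9)
        assert a == b

    def test_different_seeds_differ(self, lbw):
        a = simulate_herd(lbw, years=4, burn_in=2, seed=9)
        b = simulate_herd(lbw, years=4, burn_in=2, seed=10)
        assert a != b

    def test_herd_size_stays_near_target(self, lbw, lbw_small_run):
        for rep in lbw_small_run:
            for record in rep:
                assert 0.8 * lbw.herd_size_target <= record.cows_end_of_year <= lbw.herd_size_target

    def test_cow_conservation_exact(self, lbw_small_run):
        for rep in lbw_small_run:
            for r in rep:
                assert r.cows_end_of_year == pytest.approx(
                    r.cows_start_of_year
                    + r.first_calvings
                    - r.cow_deaths
                    - r.cows_slaughtered
                )

    def test_technical_invariants(self, lbw_small_run):
        for rep in lbw_small_run:
            for r in rep:
                assert r.stillbirths <= r.calvings
                assert r.cow_years > 0
                assert all(v >= 0 for v in r.disease_cases.values())
                assert r.realized_trait_levels["mastitis"] == pytest.approx(
                    100 * r.disease_cases["mastitis"] / r.cow_years
                )

    def test_mastitis_calibration_binomial_oracle(self, lbw_small_run):
        # oracle: closed-form binomial expectation at the nominal rate
        techs = [combine_annual_results(rep) for rep in lbw_small_run]
        cases = sum(t.disease_cases["mastitis"] for t in techs)
        cow_years = sum(t.cow_years for t in techs)
        expected = 26.0 * cow_years / 100.0
        se = math.sqrt(expected)
        assert abs(cases - expected) < 3 * se

    def test_extinction_raises(self, lbw):
        doomed = dataclasses.replace(_null_params(lbw), cow_mortality=99.9)
        with pytest.raises(SimulationError, match="year"):
            simulate_batch(doomed, years=6, burn_in=0, seed=0, n_replicates=2)

    def test_null_disease_model_increases_milk(self, lbw, prices_lbw):
        # common random numbers: same seed, diseases on vs off
        healthy = dataclasses.replace(
            lbw,
            incidence_per_100cy={d: 0.0 for d in lbw.incidence_per_100cy},
            oestrus_scale_cows=compute_repro_calibration(lbw)[0],
            heifer_breeding_start_weeks=compute_repro_calibration(lbw)[1],
        )
        base_frozen = dataclasses.replace(
            lbw,
            oestrus_scale_cows=healthy.oestrus_scale_cows,
            heifer_breeding_start_weeks=healthy.heifer_breeding_start_weeks,
        )
        out_base = simulate_batch(base_frozen, years=6, burn_in=2, seed=5, n_replicates=10)
        out_healthy = simulate_batch(healthy, years=6, burn_in=2, seed=5, n_replicates=10)
        base_techs = [combine_annual_results(r) for r in out_base]
        healthy_techs = [combine_annual_results(r) for r in out_healthy]
        assert all(sum(t.disease_cases.values()) == 0 for t in healthy_techs)
        base_ecm = np.mean([t.realized_trait_levels["ecm"] for t in base_techs])
        healthy_ecm = np.mean([t.realized_trait_levels["ecm"] for t in healthy_techs])
        assert healthy_ecm > base_ecm


class TestReproductionCalibration:
    @pytest.mark.parametrize("breed_fixture", ["lbw", "lr", "lrog"])
    def test_calving_interval_within_10_days(self, request, breed_fixture):
        params = request.getfixturevalue(breed_fixture)
        out = simulate_batch(params, years=14, burn_in=4, seed=17, n_replicates=40)
        techs = [combine_annual_results(r) for r in out]
        ci = sum(t.calving_interval_sum_days for t in techs) / sum(
            t.calving_interval_count for t in techs
        )
        assert abs(ci - params.calving_interval_days) <= 10

    def test_scale_solves_target_wait(self, lbw):
        scale, start_h = compute_repro_calibration(lbw)
        assert 0 < scale < 3
        assert 26 <= start_h <= 110


class TestAnnualAggregate:
    def test_empty_year(self):
        record = annual_aggregate({}, replicate_id=0, year_index=0)
        assert record.cow_years == 0
        assert record.kg_ecm_delivered == 0
        assert record.realized_trait_levels["ecm"] == 0

    def test_realized_incidence_arithmetic(self):
        counts = {
            "cow_weeks": 195.3 * WEEKS_PER_YEAR,
            "disease_cases": {"mastitis": 10.0},
            "calvings": 50.0,
            "stillbirths": 3.0,
        }
        record = annual_aggregate(counts, replicate_id=1, year_index=2)
        assert record.realized_trait_levels["mastitis"] == pytest.approx(5.1203, abs=1e-3)
        assert record.realized_trait_levels["stillbirth"] == pytest.approx(6.0)

    def test_stillbirths_cannot_exceed_calvings(self):
        with pytest.raises(ValidationError):
            annual_aggregate(
                {"calvings": 2.0, "stillbirths": 3.0, "cow_weeks": 52.0},
                replicate_id=0,
                year_index=0,
            )

    def test_combine_pools_counts(self, lbw_small_run):
        rep = lbw_small_run.replicate(0)
        total = combine_annual_results(rep)
        assert total.calvings == sum(r.calvings for r in rep)
        assert total.cow_years == pytest.approx(sum(r.cow_years for r in rep))

    def test_dataframe_export(self, lbw_small_run):
        df = lbw_small_run.to_dataframe()
        assert len(df) == 20 * 5
        assert "cases_mastitis" in df.columns
        assert "level_ecm" in df.columns


def test_annual_result_is_plain_data(lbw_small_run):
    r = lbw_small_run.replicate(0)[0]
    d = dataclasses.asdict(r)
    assert isinstance(d["disease_cases"], dict)
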