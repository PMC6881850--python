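"""Cost accounting, discounting, the scenario engine, and ICER arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import scitsim as ss
from scitsim.economics import (
    DOMINANT,
    CostTable,
    DiscountSpec,
    ModelInputs,
    ScitCostSchedule,
    annual_state_cost,
    compare_to_status_quo,
    discount,
    icer,
    run_scenario,
    scit_mean_cost,
)
from scitsim.population import IncidenceSchedule, PrevalenceTable
from scitsim.states import (
    AgeGroup,
    AllergyType,
    DiseaseState,
    N_STATES,
    st_stratum,
)
from scitsim.synthetic import default_transition_params


class TestAnnualStateCost:
    def test_hundred_adults_in_state_a_cost_800(self):
        v = np.zeros(N_STATES)
        v[int(DiseaseState.A)] = 100.0
        cohorts = {st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL): v}
        assert annual_state_cost(cohorts, CostTable()) == pytest.approx(800.0)

    def test_healthy_and_dead_cost_nothing(self):
        v = np.zeros(N_STATES)
        v[int(DiseaseState.E)] = 1e6
        v[int(DiseaseState.F)] = 1e6
        cohorts = {st_stratum(AgeGroup.CHILDREN, AllergyType.PERENNIAL): v}
        assert annual_state_cost(cohorts, CostTable()) == 0.0

    def test_mixed_occupancy_matches_loop_oracle(self, rng):
        table = CostTable()
        cohorts = {
            st_stratum(g, t): rng.uniform(0, 1000, N_STATES)
            for g in AgeGroup
            for t in AllergyType
        }
        expected = 0.0
        for key, v in cohorts.items():
            for s in (DiseaseState.A, DiseaseState.B, DiseaseState.C, DiseaseState.D):
                expected += v[int(s)] * table.state_cost[(key.age_group, s)]
        assert annual_state_cost(cohorts, table) == pytest.approx(expected)


class TestScitCost:
    def test_year_one_mean_is_382(self):
        assert scit_mean_cost(ScitCostSchedule(), 1) == pytest.approx(382.0)

    def test_years_two_three_mean_is_371(self):
        s = ScitCostSchedule()
        assert scit_mean_cost(s, 2) == pytest.approx(371.0)
        assert scit_mean_cost(s, 3) == pytest.approx(371.0)

    def test_equal_application_arms_return_common_cost(self):
        s = ScitCostSchedule(preseasonal=(300, 300, 300), perennial=(300, 300, 300))
        assert scit_mean_cost(s, 2) == 300.0

    def test_invalid_therapy_year(self):
        with pytest.raises(ValueError, match="therapy_year"):
            scit_mean_cost(ScitCostSchedule(), 4)

    def test_type_specific_mode(self):
        s = ScitCostSchedule(mean_mode=False)
        assert s.cost(1, AllergyType.SEASONAL) == 262.0
        assert s.cost(1, AllergyType.PERENNIAL) == 502.0


class TestDiscount:
    def test_base_year_is_undiscounted(self):
        assert discount(100.0, 2011, DiscountSpec()) == 100.0

    def test_one_year_at_two_percent(self):
        assert discount(102.0, 2012, DiscountSpec()) == pytest.approx(100.0)

    def test_closed_form_at_horizon_end(self):
        assert discount(100.0, 2050, DiscountSpec()) == pytest.approx(
            100.0 / 1.02**39
        )

    def test_year_before_base_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            discount(1.0, 2010, DiscountSpec())

    def test_discounted_total_decreases_in_rate(self):
        """Present value of a future cost stream falls as the rate rises."""
        stream = {year: 100.0 for year in range(2012, 2051)}
        totals = [
            sum(discount(c, y, DiscountSpec(annual_rate=r)) for y, c in stream.items())
            for r in (0.0, 0.01, 0.02, 0.05, 0.10)
        ]
        assert all(a > b for a, b in zip(totals, totals[1:]))


class TestIcer:
    def test_scenario_3_table_row(self):
        assert icer(98_964_793, 288_213) == 343

    def test_scenario_4_table_row(self):
        assert icer(131_341_777, 424_559) == 309

    def test_cost_saving_scenarios_dominate(self):
        assert icer(-1_250_059, 32_794) == DOMINANT
        assert icer(-5_732_459, 67_126) == DOMINANT

    def test_non_positive_effect_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            icer(1000.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            icer(1000.0, -5.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cost=st.floats(1, 1e9),
        healed=st.floats(1, 1e7),
        k=st.floats(0.01, 100),
    )
    def test_scaling_both_arguments_preserves_the_ratio(self, cost, healed, k):
        assert abs(icer(k * cost, k * healed) - icer(cost, healed)) <= 1


class TestCompareToStatusQuo:
    def _result(self, name, cost, healed):
        years = range(2011, 2051)
        df = pd.DataFrame(
            {
                "diseased": 0.0,
                "healed": healed,
                "total_cost": cost,
                "total_cost_discounted": cost,
                "scit_cost": 0.0,
            },
            index=pd.Index(years, name="year"),
        )
        return ss.RunResult(name, df, {})

    def test_identical_results_give_zero_differences(self):
        results = {
            "status_quo": self._result("status_quo", 500.0, 10.0),
            "other": self._result("other", 500.0, 10.0),
        }
        table = compare_to_status_quo(results)
        assert table.loc["other", "delta_mean_annual_cost"] == 0.0
        assert table.loc["other", "delta_mean_annual_healed"] == 0.0
        assert table.loc["other", "cost_per_additional_healed"] == "n/a"

    def test_injected_deltas_are_recovered(self):
        results = {
            "status_quo": self._result("status_quo", 1_000.0, 100.0),
            "up": self._result("up", 1_500.0, 125.0),
            "saving": self._result("saving", 900.0, 110.0),
        }
        table = compare_to_status_quo(results)
        assert table.loc["up", "delta_mean_annual_cost"] == pytest.approx(500.0)
        assert table.loc["up", "delta_mean_annual_healed"] == pytest.approx(25.0)
        assert table.loc["up", "cost_per_additional_healed"] == 20
        assert table.loc["saving", "cost_per_additional_healed"] == DOMINANT

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(KeyError, match="status_quo"):
            compare_to_status_quo({"x": self._result("x", 1.0, 1.0)})


class TestRunScenario:
    def _inputs(self, pool, **kwargs):
        return ModelInputs(
            initial_pool=pool,
            matrices=default_transition_params(effect_size=0.5),
            incidence=IncidenceSchedule({}),
            **kwargs,
        )

    def test_empty_model_stays_empty(self):
        inputs = self._inputs({})
        res = run_scenario(ss.builtin_scenarios()[0], inputs)
        assert (res.by_year[["diseased", "healed", "total_cost"]] == 0).all().all()

    def test_identity_matrices_zero_supply_follow_ageing_only(self):
        v = np.zeros(N_STATES)
        v[int(DiseaseState.C)] = 470.0
        pool = {st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL): v}
        inputs = ModelInputs(
            initial_pool=pool,
            matrices={
                k: np.eye(N_STATES)
                for k in default_transition_params(effect_size=0.0)
            },
            incidence=IncidenceSchedule({}),
        )
        res = run_scenario(ss.no_scit_scenario(), inputs)
        expected = 470.0 * (1 - 1 / 47) ** np.arange(40)
        np.testing.assert_allclose(res.by_year["diseased"].to_numpy(), expected)

    def test_rerun_is_deterministic(self, toy_config):
        prepared = ss.prepare(toy_config)
        spec = ss.builtin_scenarios()[0]
        a = run_scenario(spec, prepared.inputs).by_year
        b = run_scenario(spec, prepared.inputs).by_year
        pd.testing.assert_frame_equal(a, b)

    def test_total_cost_is_state_plus_scit_exactly(self, desk_results):
        for res in desk_results.values():
            df = res.by_year
            np.testing.assert_array_equal(
                df["total_cost"].to_numpy(),
                (df["state_cost"] + df["scit_cost"]).to_numpy(),
            )

    def test_discounted_total_never_exceeds_undiscounted(self, desk_results):
        for res in desk_results.values():
            df = res.by_year
            assert (df["total_cost_discounted"] <= df["total_cost"] + 1e-9).all()
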