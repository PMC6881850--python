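"""Scenario definitions, supply-rate interpolation and SCIT allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scitsim.scenarios import (
    BASELINE_RATES_2011,
    ScenarioSpec,
    SupplySchedule,
    allocate_scit,
    builtin_scenarios,
    no_scit_scenario,
    supply_rate,
)
from scitsim.states import (
    AgeGroup,
    AllergyType,
    Arm,
    DiseaseState,
    N_STATES,
    StratumKey,
    scit_stratum,
    st_stratum,
)

ADULT_SEASONAL = (AgeGroup.ADULTS, AllergyType.SEASONAL)


@pytest.fixture(scope="module")
def scenarios():
    return {s.name: s for s in builtin_scenarios()}


class TestBuiltinScenarios:
    def test_exactly_five_scenarios(self, scenarios):
        assert set(scenarios) == {
            "status_quo", "scenario_1", "scenario_2", "scenario_3", "scenario_4",
        }

    def test_baseline_rates_2011(self, scenarios):
        sched = scenarios["status_quo"].schedule
        assert sched.rate_2011[(AgeGroup.CHILDREN, AllergyType.SEASONAL)] == 0.05
        assert sched.rate_2011[(AgeGroup.ADOLESCENTS, AllergyType.SEASONAL)] == 0.15
        assert sched.rate_2011[ADULT_SEASONAL] == 0.20
        assert sched.rate_2011[(AgeGroup.ADOLESCENTS, AllergyType.PERENNIAL)] == 0.10

    def test_status_quo_targets_2030(self, scenarios):
        sched = scenarios["status_quo"].schedule
        assert sched.target_year == 2030
        assert sched.rate_target[ADULT_SEASONAL] == 0.30
        assert sched.rate_target[(AgeGroup.CHILDREN, AllergyType.PERENNIAL)] == 0.05

    def test_scenario_1_triples_2011_rates_by_2020(self, scenarios):
        sched = scenarios["scenario_1"].schedule
        assert sched.target_year == 2020
        assert sched.rate_target[ADULT_SEASONAL] == pytest.approx(0.60)
        for k, v in BASELINE_RATES_2011.items():
            assert sched.rate_target[k] == pytest.approx(3 * v)

    def test_scenario_2_reaches_75_percent_by_2020(self, scenarios):
        sched = scenarios["scenario_2"].schedule
        assert sched.target_year == 2020
        assert all(v == 0.75 for v in sched.rate_target.values())

    def test_eligible_state_sets(self, scenarios):
        cd = {DiseaseState.C, DiseaseState.D}
        assert scenarios["status_quo"].eligible_states == cd
        assert scenarios["scenario_1"].eligible_states == cd
        assert scenarios["scenario_2"].eligible_states == cd
        assert scenarios["scenario_3"].eligible_states == cd | {DiseaseState.B}
        assert scenarios["scenario_4"].eligible_states == cd | {
            DiseaseState.A, DiseaseState.B,
        }

    def test_empty_eligible_set_rejected(self, scenarios):
        with pytest.raises(ValueError, match="non-empty"):
            ScenarioSpec("bad", scenarios["status_quo"].schedule, frozenset())


class TestSupplyRate:
    def test_endpoint_and_plateau_values(self, scenarios):
        sched = scenarios["status_quo"].schedule
        assert supply_rate(sched, *ADULT_SEASONAL, 2011) == pytest.approx(0.20)
        assert supply_rate(sched, *ADULT_SEASONAL, 2030) == pytest.approx(0.30)
        assert supply_rate(sched, *ADULT_SEASONAL, 2040) == pytest.approx(0.30)

    def test_linear_interpolation_midway(self, scenarios):
        sched = scenarios["scenario_1"].schedule
        expected = 0.05 + (0.15 - 0.05) * 5 / 9
        assert supply_rate(
            sched, AgeGroup.CHILDREN, AllergyType.SEASONAL, 2016
        ) == pytest.approx(expected)

    def test_year_out_of_range(self, scenarios):
        with pytest.raises(ValueError, match="2010"):
            supply_rate(scenarios["status_quo"].schedule, *ADULT_SEASONAL, 2010)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        year_a=st.integers(2011, 2050),
        year_b=st.integers(2011, 2050),
    )
    def test_non_decreasing_when_target_above_start(self, year_a, year_b):
        sched = builtin_scenarios()[0].schedule  # status quo: targets >= 2011 rates
        lo, hi = sorted((year_a, year_b))
        assert supply_rate(sched, *ADULT_SEASONAL, lo) <= supply_rate(
            sched, *ADULT_SEASONAL, hi
        ) + 1e-12


class TestAllocateScit:
    def _cohorts(self, per_state):
        key = st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL)
        v = np.zeros(N_STATES)
        v[:4] = per_state
        return {key: v}

    def _spec(self, rate, eligible):
        rates = {k: rate for k in BASELINE_RATES_2011}
        return ScenarioSpec(
            "fixture", SupplySchedule(rates, rates, 2030), frozenset(eligible)
        )

    def test_zero_rate_changes_nothing(self):
        cohorts = self._cohorts([10, 20, 30, 40])
        spec = self._spec(0.0, {DiseaseState.C, DiseaseState.D})
        out = allocate_scit(cohorts, spec, 2015)
        for k, v in cohorts.items():
            np.testing.assert_array_equal(out[k], v)

    def test_full_uptake_moves_all_eligible(self):
        key = st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL)
        v = np.zeros(N_STATES)
        v[int(DiseaseState.C)] = 100.0
        spec = self._spec(1.0, {DiseaseState.C, DiseaseState.D})
        out = allocate_scit({key: v}, spec, 2015)
        y1 = scit_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL, 1)
        assert out[key][int(DiseaseState.C)] == 0.0
        assert out[y1][int(DiseaseState.C)] == 100.0

    def test_partial_uptake_hand_computed(self):
        """Rate 0.3 on eligible B,C,D over counts (10,20,30,40) moves (0,6,9,12)."""
        cohorts = self._cohorts([10.0, 20.0, 30.0, 40.0])
        spec = self._spec(0.3, {DiseaseState.B, DiseaseState.C, DiseaseState.D})
        out = allocate_scit(cohorts, spec, 2015)
        st_key = st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL)
        y1 = scit_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL, 1)
        np.testing.assert_allclose(out[st_key][:4], [10.0, 14.0, 21.0, 28.0])
        np.testing.assert_allclose(out[y1][:4], [0.0, 6.0, 9.0, 12.0])
        total = sum(v.sum() for v in out.values())
        assert total == pytest.approx(100.0)

    def test_ongoing_scit_untouched(self):
        st_key = st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL)
        y2 = scit_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL, 2)
        v_st = np.zeros(N_STATES)
        v_st[2] = 50.0
        v_y2 = np.zeros(N_STATES)
        v_y2[2] = 30.0
        spec = self._spec(0.5, {DiseaseState.C})
        out = allocate_scit({st_key: v_st, y2: v_y2}, spec, 2015)
        np.testing.assert_array_equal(out[y2], v_y2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        rate=st.floats(0, 1),
        counts=st.lists(st.floats(0, 1e6), min_size=4, max_size=4),
        eligible=st.sets(
            st.sampled_from([DiseaseState.A, DiseaseState.B, DiseaseState.C,
                             DiseaseState.D]),
            min_size=1,
        ),
    )
    def test_persons_conserved_for_all_rates_and_sets(self, rate, counts, eligible):
        cohorts = self._cohorts(counts)
        spec = self._spec(rate, eligible)
        out = allocate_scit(cohorts, spec, 2020)
        before = sum(v.sum() for v in cohorts.values())
        after = sum(v.sum() for v in out.values())
        assert after == pytest.approx(before, rel=1e-12, abs=1e-9)

    def test_stock_mode_enrolls_only_the_shortfall(self):
        st_key = st_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL)
        y1_key = scit_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL, 1)
        y2_key = scit_stratum(AgeGroup.ADULTS, AllergyType.SEASONAL, 2)
        v_st = np.zeros(N_STATES)
        v_st[2] = 60.0
        v_y2 = np.zeros(N_STATES)
        v_y2[2] = 40.0
        spec = self._spec(0.5, {DiseaseState.C})
        out = allocate_scit({st_key: v_st, y2_key: v_y2}, spec, 2015, mode="stock")
        # coverage target 0.5 * (60 + 40) = 50, already 40 under therapy
        assert out[y1_key][2] == pytest.approx(10.0)
        assert out[st_key][2] == pytest.approx(50.0)
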