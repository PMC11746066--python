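"""Cohort engine: state space, transition rows, trace, accumulation."""

import numpy as np
import pytest

import tkicea as t
from tkicea.markov import (
    aggregate_occupancy,
    build_state_space,
    build_transition_matrix,
    run_trace,
)
from tkicea.parameters import Strategy, SwitchRule


def stay_forever_spec(cost=100.0, utility=0.8, rate=0.0, horizon=2):
    """Base case bent into a single-absorbing-state model: the whole cohort
    stays in first-line CP with certainty."""
    spec = t.builtin_basecase()
    d = spec.drugs["imatinib"]
    d.os_cp, d.ccyr, d.annual_cost = 1.0, 1.0, cost
    spec.utilities.u_cp1 = utility
    spec.costs.consult = spec.costs.monitoring = 0.0
    spec.costs.adverse_events = []
    spec.econ.discount_rate = rate
    spec.econ.horizon_cycles = horizon
    return spec


class TestStateSpace:
    def test_imatinib_strategy_expanded_states(self, basecase):
        space = build_state_space(basecase, "imatinib")
        assert set(space.labels) == {
            "CP1", "CP2:nilotinib", "CP2:dasatinib",
            "APBP:nilotinib", "APBP:dasatinib", "SCT_Y1", "SCT_POST", "DEATH"}
        assert space.first_drug == "imatinib"

    def test_second_generation_strategies_switch_back(self, basecase):
        assert build_state_space(basecase, "nilotinib").destinations == (
            "imatinib", "dasatinib")
        assert build_state_space(basecase, "dasatinib").destinations == (
            "imatinib", "nilotinib")

    def test_unknown_strategy_rejected(self, basecase):
        with pytest.raises(KeyError):
            build_state_space(basecase, "bosutinib")

    def test_empty_switch_rule_rejected(self, basecase):
        spec = basecase.clone()
        spec.strategies.append(
            Strategy("lonely", "imatinib", SwitchRule("imatinib", {})))
        with pytest.raises(ValueError, match="empty switch rule"):
            build_state_space(spec, "lonely")

    def test_aggregation_recovers_five_clinical_states(self, basecase_results):
        agg = aggregate_occupancy(basecase_results["imatinib"].trace)
        assert list(agg.columns) == ["FIRST_LINE", "SECOND_LINE", "APBP",
                                     "SCT", "DEATH"]
        np.testing.assert_allclose(agg.sum(axis=1), 1.0, atol=1e-12)


class TestTransitionMatrix:
    def test_cp1_row_death_first_ordering(self, basecase):
        # die with 1-0.977; survivors fail with 1-0.67 and split 50/50
        space = build_state_space(basecase, "imatinib")
        M = build_transition_matrix(basecase, "imatinib")
        row = M[space.i_cp1]
        assert row[space.i_death] == pytest.approx(0.023, abs=1e-12)
        assert row[space.i_cp1] == pytest.approx(0.977 * 0.67, abs=1e-12)
        for d in ("nilotinib", "dasatinib"):
            assert row[space.i_cp2(d)] == pytest.approx(0.977 * 0.33 * 0.5,
                                                        abs=1e-12)

    def test_apbp_row_without_transplant(self, basecase):
        spec = basecase.clone()
        spec.transplant.p_receive = 0.0
        space = build_state_space(spec, "imatinib")
        M = build_transition_matrix(spec, "imatinib")
        row = M[space.i_apbp("nilotinib")]
        assert row[space.i_death] == pytest.approx(1 - 0.052, abs=1e-12)
        assert row[space.i_apbp("nilotinib")] == pytest.approx(0.052, abs=1e-12)

    def test_perfect_response_keeps_cohort_in_cp1(self, basecase):
        spec = basecase.clone()
        spec.drugs["imatinib"].os_cp = 1.0
        spec.drugs["imatinib"].ccyr = 1.0
        space = build_state_space(spec, "imatinib")
        M = build_transition_matrix(spec, "imatinib")
        expected = np.zeros(space.n)
        expected[space.i_cp1] = 1.0
        np.testing.assert_allclose(M[space.i_cp1], expected, atol=1e-15)

    @pytest.mark.parametrize("strategy", ["imatinib", "nilotinib", "dasatinib"])
    def test_rows_are_distributions_and_death_absorbs(self, basecase, strategy):
        space = build_state_space(basecase, strategy)
        M = build_transition_matrix(basecase, strategy)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
        assert (M >= 0).all()
        assert M[space.i_death, space.i_death] == 1.0

    def test_first_cycle_only_switches_once(self, basecase):
        spec = basecase.clone()
        spec.econ.conventions.switch_mode = "first_cycle_only"
        res = t.run_strategy(spec, "imatinib")
        space = res.trace.state_space
        cp2 = [space.i_cp2(d) for d in space.destinations]
        assert res.trace.entrants[1, cp2].sum() > 0
        np.testing.assert_allclose(res.trace.entrants[2:, cp2], 0.0, atol=1e-15)


class TestTrace:
    def test_two_state_toy_matrix_power(self):
        M = np.array([[0.5, 0.5], [0.0, 1.0]])
        trace = run_trace(M, horizon=2)
        np.testing.assert_allclose(trace.occupancy[2], [0.25, 0.75])
        np.testing.assert_allclose(trace.entrants[1], [0.0, 0.5])

    @pytest.mark.parametrize("strategy", ["imatinib", "nilotinib", "dasatinib"])
    def test_conservation_and_death_monotonicity(self, basecase_results, strategy):
        trace = basecase_results[strategy].trace
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        death = trace.occupancy[:, trace.state_space.i_death]
        assert (np.diff(death) >= -1e-15).all()
        assert (trace.entrants >= -1e-15).all()

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            run_trace(np.eye(2), horizon=0)


class TestAccumulate:
    def test_undiscounted_absorbing_state_totals(self):
        res = t.run_strategy(stay_forever_spec(), "imatinib")
        assert res.total_cost == pytest.approx(200.0)
        assert res.total_qalys == pytest.approx(1.6)

    def test_mid_cycle_discounting_closed_form(self):
        res = t.run_strategy(stay_forever_spec(rate=0.05), "imatinib")
        expected = 100.0 * (1.05 ** -0.5 + 1.05 ** -1.5)
        assert res.total_cost == pytest.approx(expected, rel=1e-12)
        assert res.total_qalys == pytest.approx(0.8 / 100.0 * expected, rel=1e-12)

    def test_end_cycle_discounting_closed_form(self):
        spec = stay_forever_spec(rate=0.05)
        spec.econ.conventions.discount_timing = "end_cycle"
        res = t.run_strategy(spec, "imatinib")
        assert res.total_cost == pytest.approx(100.0 * (1.05 ** -1 + 1.05 ** -2),
                                               rel=1e-12)

    def test_zero_rate_reproduces_undiscounted_sums(self, basecase):
        spec = basecase.clone()
        spec.econ.discount_rate = 0.0
        mid = t.run_all(spec)
        spec.econ.conventions.discount_timing = "end_cycle"
        end = t.run_all(spec)
        for name in mid:
            assert mid[name].total_cost == pytest.approx(end[name].total_cost,
                                                         rel=1e-12)
            assert mid[name].total_qalys == pytest.approx(end[name].total_qalys,
                                                          rel=1e-12)

    def test_total_cost_equals_component_sum(self, basecase_results):
        for res in basecase_results.values():
            assert res.total_cost == pytest.approx(sum(res.components().values()),
                                                   abs=1e-6)

    def test_qalys_bounded_by_horizon_times_max_utility(self, basecase,
                                                        basecase_results):
        cap = basecase.econ.horizon_cycles * 0.89
        for res in basecase_results.values():
            assert 0 < res.total_qalys <= cap

    def test_mismatched_trace_and_strategy_rejected(self, basecase,
                                                    basecase_results):
        with pytest.raises(ValueError, match="built for strategy"):
            t.accumulate(basecase, "nilotinib", basecase_results["imatinib"].trace)

    def test_lower_utility_strictly_lowers_qalys(self, basecase, basecase_results):
        worse = t.perturb(basecase, "utilities.u_cp1", -0.1)
        for name, res in t.run_all(worse).items():
            assert res.total_qalys < basecase_results[name].total_qalys


def test_aggregated_five_state_oracle_equivalence(basecase):
    """With identical drugs and constant post-SCT survival, the expanded trace
    summed to the five clinical states must equal a trace run directly on the
    hand-built five-state matrix."""
    spec = basecase.clone()
    for d in spec.drugs.values():
        d.annual_cost, d.ccyr, d.os_cp, d.p_apbp = 5000.0, 0.7, 0.95, 0.04
    spec.econ.conventions.os_post_mode = "constant"
    res = t.run_strategy(spec, "imatinib")
    agg = aggregate_occupancy(res.trace)

    os_, cc, pp = 0.95, 0.7, 0.04
    pr, osA, osY = spec.transplant.p_receive, spec.apbp.os, spec.transplant.os_y1
    M5 = np.array([
        [os_ * cc, os_ * (1 - cc), 0, 0, 1 - os_],
        [0, os_ * (1 - pp), os_ * pp, 0, 1 - os_],
        [0, 0, (1 - pr) * osA, pr, (1 - pr) * (1 - osA)],
        [0, 0, 0, osY, 1 - osY],
        [0, 0, 0, 0, 1.0],
    ])
    oracle = run_trace(M5, spec.econ.horizon_cycles)
    np.testing.assert_allclose(agg.to_numpy(), oracle.occupancy, atol=1e-12)
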