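"""Cohort engine: transition matrices, occupancy propagation, accounting.

Includes an exhaustive path-enumeration oracle: for short horizons the state
distribution is recomputed by summing the probability of every possible state
sequence, independently of the matrix-recursion code path.
"""

import itertools

import numpy as np
import pytest

from zoster_cea import (
    Strategy,
    build_transition_matrix,
    evaluate_all,
    make_synthetic_parameters,
    run_cohort,
    summarize,
)
from zoster_cea.cohort import COST_CATEGORIES, N_STATES, CohortTrace, HealthState, discounted_total
from zoster_cea.errors import ZosterCeaError


def enumerate_occupancy(params, strategy, start_age):
    """Brute-force oracle: marginal occupancy from explicit path probabilities.

    For every cycle t, sums the probability of each length-t state sequence
    starting from Healthy — no matrix recursion involved.
    """
    h = params.economics.horizon
    mats = [build_transition_matrix(params, strategy, start_age, t) for t in range(h)]
    occ = np.zeros((h + 1, N_STATES))
    occ[0, HealthState.HEALTHY] = 1.0
    for t in range(1, h + 1):
        for path in itertools.product(range(N_STATES), repeat=t):
            prob = 1.0
            prev = int(HealthState.HEALTHY)
            for k, state in enumerate(path):
                prob *= mats[k][prev, state]
                prev = state
            occ[t, path[-1]] += prob
    return occ


class TestTransitionMatrix:
    def test_zero_incidence_and_recurrence_leaves_mortality_only(self, params):
        for band in params.epidemiology.hz_incidence:
            params.epidemiology.hz_incidence[band] = 0.0
        params.epidemiology.p_recurrence = 0.0
        M = build_transition_matrix(params, Strategy.NONE, 60, 0)
        from zoster_cea.params import mortality_at

        q = mortality_at(params, 60)
        row = M[HealthState.HEALTHY]
        assert row[HealthState.HEALTHY] == pytest.approx(1 - q)
        assert row[HealthState.DEAD] == pytest.approx(q)
        assert row[HealthState.ACUTE_HZ] == 0.0

    def test_certain_death_empties_every_living_state(self, params):
        for age in params.epidemiology.all_cause_mortality:
            params.epidemiology.all_cause_mortality[age] = 1.0
        M = build_transition_matrix(params, Strategy.NONE, 70, 0)
        for s in HealthState:
            assert M[s, HealthState.DEAD] == pytest.approx(1.0)

    def test_full_protection_zeroes_incidence(self, params):
        params.efficacy_anchors["RZV"]["60-69"] = [[0, 1.0], [10, 1.0]]
        M = build_transition_matrix(params, Strategy.RZV, 60, 0)
        assert M[HealthState.HEALTHY, HealthState.ACUTE_HZ] == 0.0

    def test_rows_are_distributions(self, synth_params):
        for cycle in (0, 15, 39):
            M = build_transition_matrix(synth_params, Strategy.ZVL, 50, cycle)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((M >= 0) & (M <= 1))
        assert M[HealthState.DEAD, HealthState.DEAD] == 1.0

    def test_attained_age_crosses_bands(self, params):
        # a cohort starting at 50 must use 60-69 inputs after 10 cycles
        params.epidemiology.hz_incidence["50-59"] = 0.001
        params.epidemiology.hz_incidence["60-69"] = 0.1
        m9 = build_transition_matrix(params, Strategy.NONE, 50, 9)
        m10 = build_transition_matrix(params, Strategy.NONE, 50, 10)
        assert m10[HealthState.HEALTHY, HealthState.ACUTE_HZ] > 10 * m9[
            HealthState.HEALTHY, HealthState.ACUTE_HZ
        ]

    def test_overfull_conditional_split_is_a_parameter_error(self, params):
        params.epidemiology.p_phn_given_hz["60-69"] = 0.8
        params.epidemiology.p_other_comp_given_hz["60-69"] = 0.5
        with pytest.raises(ZosterCeaError, match="AcuteHZ"):
            build_transition_matrix(params, Strategy.NONE, 60, 0)

    def test_cycle_outside_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            build_transition_matrix(params, Strategy.NONE, 60, 40)


class TestRunCohort:
    def test_immortal_diseaseless_cohort_accrues_flat_utility(self, params):
        for band in params.epidemiology.hz_incidence:
            params.epidemiology.hz_incidence[band] = 0.0
        params.epidemiology.p_recurrence = 0.0
        for age in params.epidemiology.all_cause_mortality:
            params.epidemiology.all_cause_mortality[age] = 0.0
        trace = run_cohort(params, Strategy.NONE, 50)
        expected = [
            params.utilities.u_healthy[("50-59" if 50 + t < 60 else
                                         "60-69" if 50 + t < 70 else
                                         "70-79" if 50 + t < 80 else "80+")]
            for t in range(40)
        ]
        assert np.allclose(trace.qaly_stream, expected)
        assert trace.cost_stream.sum() == 0.0

    @pytest.mark.parametrize("strategy", list(Strategy))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, strategy, seed):
        params = make_synthetic_parameters(seed)
        params.economics.horizon = 3
        occ = run_cohort(params, strategy, 60).occupancy
        oracle = enumerate_occupancy(params, strategy, 60)
        assert np.allclose(occ, oracle, atol=1e-12)

    def test_matches_oracle_at_horizon_four(self):
        params = make_synthetic_parameters(11)
        params.economics.horizon = 4
        occ = run_cohort(params, Strategy.RZV, 50).occupancy
        oracle = enumerate_occupancy(params, Strategy.RZV, 50)
        assert np.allclose(occ, oracle, atol=1e-12)

    def test_rzv_upfront_cost_is_two_full_doses(self, base_params):
        trace = run_cohort(base_params, Strategy.RZV, 60)
        assert trace.cost_streams["vaccine"][0] == pytest.approx(2 * 453.55)
        assert trace.cost_streams["admin"][0] == pytest.approx(2 * 4.24)
        assert trace.cost_streams["vaccine"][1:].sum() == 0.0

    def test_partial_compliance_weights_dose_cost(self, params):
        params.economics.compliance_two_dose = 0.2
        trace = run_cohort(params, Strategy.RZV, 60)
        # 20% pay two doses, 80% pay one
        assert trace.cost_streams["vaccine"][0] == pytest.approx(1.2 * 453.55)

    def test_zvl_single_dose_cost(self, base_params):
        trace = run_cohort(base_params, Strategy.ZVL, 60)
        assert trace.cost_streams["vaccine"][0] == pytest.approx(194.28)
        assert trace.cost_streams["admin"][0] == pytest.approx(4.24)

    @pytest.mark.parametrize("seed", range(25))
    def test_occupancy_conservation_fuzzed(self, seed):
        params = make_synthetic_parameters(seed)
        trace = run_cohort(params, Strategy.ZVL, 50)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert trace.occupancy[0, HealthState.HEALTHY] == 1.0
        for cat in COST_CATEGORIES:
            assert np.all(trace.cost_streams[cat] >= 0)

    def test_trace_dataframe_export(self, base_params, tmp_path):
        trace = run_cohort(base_params, Strategy.RZV, 70)
        df = trace.to_dataframe()
        assert len(df) == base_params.economics.horizon
        assert {"cycle", "occ_healthy", "new_hz_episodes", "cost_vaccine", "qalys"} <= set(
            df.columns
        )
        df.to_csv(tmp_path / "trace.csv", index=False)  # exportable

    def test_half_cycle_correction_shrinks_first_cycle_qalys(self, params):
        plain = run_cohort(params, Strategy.NONE, 60).qaly_stream[0]
        params.model.half_cycle_correction = True
        corrected = run_cohort(params, Strategy.NONE, 60).qaly_stream[0]
        assert corrected < plain  # some of the cohort dies within the cycle


class TestSummarize:
    def test_zero_discount_equals_raw_sums(self, params):
        params.economics.discount_rate = 0.0
        trace = run_cohort(params, Strategy.ZVL, 60)
        res = summarize(trace, params)
        assert res.total_cost_per_1000 == pytest.approx(trace.cost_stream.sum() * 1000)
        assert res.total_qalys_per_1000 == pytest.approx(trace.qaly_stream.sum() * 1000)

    def test_cycle_zero_cost_is_undiscounted(self):
        assert discounted_total(np.array([500.0, 0, 0]), 0.05) == pytest.approx(500.0)

    def test_known_one_cycle_discount(self):
        assert discounted_total(np.array([0.0, 105.0]), 0.05) == pytest.approx(100.0)

    def test_counts_are_undiscounted_but_money_is(self, params):
        trace = run_cohort(params, Strategy.NONE, 60)
        res_r5 = summarize(trace, params)
        params.economics.discount_rate = 0.0
        res_r0 = summarize(trace, params)
        assert res_r0.cases_per_1000 == res_r5.cases_per_1000
        assert res_r0.total_cost_per_1000 > res_r5.total_cost_per_1000

    @pytest.mark.parametrize("start_age", [50, 60, 70, 80])
    def test_vaccination_dominance_direction(self, base_params, start_age):
        """With positive efficacy and no utility penalty, vaccinated arms have
        no more lifetime episodes and no fewer QALYs than no vaccination."""
        results = evaluate_all(base_params, start_age)
        ref = results[Strategy.NONE]
        for strat in (Strategy.ZVL, Strategy.RZV):
            assert results[strat].cases_per_1000 <= ref.cases_per_1000
            assert results[strat].phn_per_1000 <= ref.phn_per_1000
            assert results[strat].total_qalys_per_1000 >= ref.total_qalys_per_1000

    def test_discounted_totals_monotone_in_rate(self, base_params):
        trace = run_cohort(base_params, Strategy.RZV, 60)
        totals = []
        for r in (0.0, 0.03, 0.05, 0.08):
            totals.append(discounted_total(trace.qaly_stream, r))
        assert totals == sorted(totals, reverse=True)
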