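"""Cohort engine: matrices, calibration, trace accrual and oracles."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mncea.markov import (
    ALIVE,
    CalibrationError,
    ModelStructureError,
    StrategyDef,
    build_strategy,
    build_transition_matrix,
    calibrate_cycle_probability,
    calibrate_remission_probs,
    evaluate_strategies,
    expected_ae_cost,
    rtx_induction_cost,
    run_cohort,
    shared_cycle_probabilities,
)
from mncea.parameters import (
    N_STATES,
    CycleConvention,
    HealthState as S,
    ParameterError,
    annual_prob_to_cycle_prob,
)

ZERO_SHARED = {k: 0.0 for k in (
    "hd_entry", "pd_entry", "hd_to_pd", "pd_to_hd",
    "hd_to_kt", "pd_to_kt", "hd_death", "pd_death", "kt_death",
)}


def toy_strategy(matrix, utilities, state_costs=None, lumps=None):
    return StrategyDef(
        name="TOY",
        transition_matrix=matrix,
        utilities=np.asarray(utilities, dtype=float),
        state_cost_terms=[(None, np.asarray(state_costs, dtype=float))]
        if state_costs is not None
        else [],
        lumps=lumps or [],
    )


class TestCalibration:
    def test_zero_target(self):
        assert calibrate_cycle_probability(0.0, 12) == 0.0

    @pytest.mark.parametrize(
        "target,expected",
        [(0.6415, 0.0819336), (0.2286, 0.0213949)],
    )
    def test_closed_form_against_compounding_oracle(self, target, expected):
        p = calibrate_cycle_probability(target, 12)
        assert p == pytest.approx(expected, abs=2e-6)
        assert 1.0 - (1.0 - p) ** 12 == pytest.approx(target, abs=1e-9)

    def test_target_at_or_above_one_rejected(self):
        with pytest.raises(ParameterError):
            calibrate_cycle_probability(1.0, 12)

    @pytest.mark.parametrize("arm", ["rtx", "tac"])
    def test_joint_calibration_inverts_published_proportions(self, table, arm):
        """12-cycle occupancy of the full matrix hits the 12-month targets."""
        v = table.values()
        shared = shared_cycle_probabilities(v)
        p_rel = calibrate_cycle_probability(v[f"calib.{arm}_relapse_12m"], 12)
        q_cr, q_pr = calibrate_remission_probs(
            v[f"calib.{arm}_cr_12m"], v[f"calib.{arm}_pr_12m"], p_rel, shared
        )
        mat = build_transition_matrix(q_cr, q_pr, p_rel, shared)
        occ = np.zeros(N_STATES)
        occ[S.ACTIVE] = 1.0
        for _ in range(12):
            occ = occ @ mat
        assert occ[S.COMPLETE_REMISSION] == pytest.approx(
            v[f"calib.{arm}_cr_12m"], abs=1e-6
        )
        assert occ[S.PARTIAL_REMISSION] == pytest.approx(
            v[f"calib.{arm}_pr_12m"], abs=1e-6
        )

    def test_infeasible_targets_raise_or_mask(self):
        with pytest.raises(CalibrationError):
            calibrate_remission_probs(0.7, 0.4, 0.0, ZERO_SHARED)
        _, _, ok = calibrate_remission_probs(
            np.array([0.7, 0.5]), np.array([0.4, 0.2]), 0.0, ZERO_SHARED, on_fail="mask"
        )
        assert list(ok) == [False, True]


class TestTransitionMatrix:
    def test_rows_are_stochastic_and_death_absorbing(self, table):
        v = table.values()
        shared = shared_cycle_probabilities(v)
        mat = build_transition_matrix(0.08, 0.03, 0.003, shared)
        np.testing.assert_allclose(mat.sum(axis=-1), 1.0, atol=1e-12)
        assert np.all((mat >= 0) & (mat <= 1))
        expected_death = np.zeros(N_STATES)
        expected_death[S.DEATH] = 1.0
        np.testing.assert_array_equal(mat[S.DEATH], expected_death)

    def test_hemodialysis_row_uses_converted_annual_rates(self, table):
        v = table.values()
        shared = shared_cycle_probabilities(v)
        mat = build_transition_matrix(0.0, 0.0, 0.0, shared)
        row = mat[S.HEMODIALYSIS]
        assert row[S.DEATH] == pytest.approx(1 - (1 - 0.0422) ** (1 / 12), abs=1e-10)
        assert row[S.PERITONEAL_DIALYSIS] == pytest.approx(
            1 - (1 - 0.0032) ** (1 / 12), abs=1e-10
        )
        assert row[S.KIDNEY_TRANSPLANT] == pytest.approx(
            1 - (1 - 0.0794) ** (1 / 12), abs=1e-10
        )
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_targets_leave_active_row_near_identity(self):
        mat = build_transition_matrix(0.0, 0.0, 0.0, ZERO_SHARED)
        np.testing.assert_array_equal(mat[S.ACTIVE], np.eye(N_STATES)[S.ACTIVE])

    def test_exits_above_one_raise_named_row(self):
        with pytest.raises(ModelStructureError, match="ACTIVE"):
            build_transition_matrix(0.7, 0.5, 0.0, ZERO_SHARED)


class TestCohortTrace:
    def test_two_state_hand_enumeration(self):
        """P(die)=0.1/cycle, utility 1, no discounting: occupancy 1, .9, .81."""
        mat = np.eye(N_STATES)
        mat[S.ACTIVE, S.ACTIVE] = 0.9
        mat[S.ACTIVE, S.DEATH] = 0.1
        util = np.zeros(N_STATES)
        util[S.ACTIVE] = 1.0
        conv = CycleConvention(horizon_years=1, annual_discount_rate=0.0)
        trace = run_cohort(toy_strategy(mat, util), conv)
        live = trace.occupancy[:4, S.ACTIVE]
        np.testing.assert_allclose(live, [1.0, 0.9, 0.81, 0.729], atol=1e-12)
        assert trace.cycle_qaly[:3].sum() == pytest.approx((1 + 0.9 + 0.81) / 12)

    def test_qaly_conservation_without_death_or_discounting(self):
        mat = np.eye(N_STATES)
        util = np.ones(N_STATES)
        conv = CycleConvention(horizon_years=5, annual_discount_rate=0.0)
        trace = run_cohort(toy_strategy(mat, util), conv)
        assert trace.cycle_qaly.sum() == pytest.approx(5.0, abs=1e-9)

    def test_unit_cost_at_cycle_12_discounts_by_one_year(self):
        mat = np.eye(N_STATES)
        conv = CycleConvention(horizon_years=1, annual_discount_rate=0.05)
        trace = run_cohort(
            toy_strategy(mat, np.zeros(N_STATES), lumps=[(12, None, 1.0)]), conv
        )
        assert trace.cycle_cost_disc[11] == pytest.approx(1 / 1.05, abs=1e-12)

    def test_discounted_totals_never_exceed_undiscounted(self, base_case):
        traces, _ = base_case
        for trace in traces.values():
            assert trace.cycle_cost_disc.sum() <= trace.cycle_cost.sum()
            assert trace.cycle_qaly_disc.sum() <= trace.cycle_qaly.sum()

    def test_trace_conservation_and_death_monotone(self, base_case):
        traces, _ = base_case
        for trace in traces.values():
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=-1), 1.0, atol=1e-10
            )
            death = trace.occupancy[..., S.DEATH]
            assert np.all(np.diff(death) >= -1e-15)
            for arr in (trace.cycle_cost_disc, trace.cycle_qaly_disc):
                assert np.all(arr >= 0)

    def test_horizon_beyond_configured_max_rejected(self, table):
        conv = table.convention()
        strat = build_strategy("RTX", table.values(), table, conv)
        with pytest.raises(ParameterError):
            run_cohort(strat, conv, horizon_years=7)

    def test_microsimulation_oracle_three_state_chain(self):
        """Cohort trace matches a 10^6-patient per-individual simulation."""
        mat = np.eye(N_STATES)
        # three-state toy: active -> remission -> (relapse-free) death
        mat[S.ACTIVE] = 0.0
        mat[S.ACTIVE, [S.ACTIVE, S.COMPLETE_REMISSION, S.DEATH]] = [0.78, 0.2, 0.02]
        mat[S.COMPLETE_REMISSION] = 0.0
        mat[S.COMPLETE_REMISSION, [S.COMPLETE_REMISSION, S.DEATH]] = [0.99, 0.01]
        util = np.zeros(N_STATES)
        util[S.ACTIVE], util[S.COMPLETE_REMISSION] = 0.7, 0.9
        conv = CycleConvention(horizon_years=1, annual_discount_rate=0.0)
        trace = run_cohort(toy_strategy(mat, util), conv)

        n = 1_000_000
        rng = np.random.default_rng(20240108)
        states = np.full(n, int(S.ACTIVE))
        qaly = np.zeros(n)
        cum = mat.cumsum(axis=1)
        for _ in range(conv.n_cycles):
            qaly += util[states] / 12.0
            u = rng.random(n)
            states = (u[:, None] > cum[states]).sum(axis=1)
        occ_sim = np.bincount(states, minlength=N_STATES) / n
        occ_model = trace.occupancy[-1]
        # binomial MC error per state
        se = np.sqrt(np.maximum(occ_model * (1 - occ_model), 1e-12) / n)
        assert np.all(np.abs(occ_sim - occ_model) <= 3 * se + 1e-9)
        qaly_se = qaly.std() / np.sqrt(n)
        assert abs(qaly.mean() - trace.cycle_qaly.sum()) <= 3 * qaly_se


class TestSchedules:
    def test_expected_ae_cost_empty_profile(self):
        assert expected_ae_cost([]) == 0.0

    def test_expected_ae_cost_published_profiles(self):
        # independent summation oracle over the published incidences/costs
        rtx = [(0.0377, 44.3751), (0.0189, 33.3), (0.0189, 425.0545), (0.0189, 7400.0)]
        assert expected_ae_cost(rtx) == pytest.approx(sum(i * c for i, c in rtx))
        assert expected_ae_cost(rtx) == pytest.approx(150.20, abs=0.01)
        tac = [(0.1143, 7400.0), (0.0286, 10000.0), (0.0286, 4000.0), (0.1429, 15.0)]
        assert expected_ae_cost(tac) == pytest.approx(1248.37, abs=0.01)

    def test_expected_ae_cost_validates_inputs(self):
        with pytest.raises(ParameterError):
            expected_ae_cost([(1.2, 10.0)])
        with pytest.raises(ParameterError):
            expected_ae_cost([(0.1, -5.0)])

    def test_rtx_induction_cost_whole_vials(self, table):
        # 1.73 m2 x 375 mg = 648.75 mg -> 7 vials x 4 doses
        cost = rtx_induction_cost(table.values(), table.settings)
        assert cost == pytest.approx(4 * 7 * 1366.2)

    def test_second_course_charged_to_pr_fraction(self, table):
        """RTX cost at the 6-month evaluation scales with PR occupancy."""
        conv = table.convention()
        strat = build_strategy("RTX", table.values(), table, conv)
        trace = run_cohort(strat, conv)
        pr_at_6 = trace.occupancy[5, S.PARTIAL_REMISSION]
        induction = rtx_induction_cost(table.values(), table.settings)
        cycle6 = trace.cycle_cost[5]
        occ6 = trace.occupancy[5]
        esrd = (
            occ6[S.HEMODIALYSIS] * table.value("cost.hd_annual")
            + occ6[S.PERITONEAL_DIALYSIS] * table.value("cost.pd_annual")
            + occ6[S.KIDNEY_TRANSPLANT] * table.value("cost.kt_annual")
        ) / 12.0
        # cycle-6 accrual = ESRD state costs + monitoring visit
        # + second course (drug + AE) x PR occupancy
        assert cycle6 >= induction * pr_at_6
        assert cycle6 == pytest.approx(esrd + induction * pr_at_6 + 155.0 * (
            1 - occ6[S.DEATH]
        ) + expected_ae_cost(
            [(table.value(i), table.value(c)) for i, c in [
                ("ae_inc.rtx_rash", "ae_cost.rash"),
                ("ae_inc.rtx_fever", "ae_cost.fever"),
                ("ae_inc.rtx_gi_infection", "ae_cost.gi_infection"),
                ("ae_inc.rtx_pneumonia", "ae_cost.pneumonia"),
            ]]
        ) * pr_at_6, rel=1e-9)

    def test_unknown_strategy_rejected(self, table):
        with pytest.raises(ParameterError):
            build_strategy("CYC", table.values(), table, table.convention())


class TestPropertyConservation:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_parameter_sets_conserve_probability(self, seed):
        """Row-stochasticity and monotone death for random valid matrices."""
        rng = np.random.default_rng(seed)
        shared = {k: float(rng.uniform(0, 0.05)) for k in ZERO_SHARED}
        q_cr, q_pr = rng.uniform(0, 0.4, 2)
        p_rel = float(rng.uniform(0, 0.3))
        mat = build_transition_matrix(q_cr, q_pr, p_rel, shared)
        util = rng.uniform(0, 1, N_STATES)
        util[S.DEATH] = 0.0
        conv = CycleConvention(horizon_years=3, annual_discount_rate=0.05)
        trace = run_cohort(toy_strategy(mat, util), conv)
        np.testing.assert_allclose(trace.occupancy.sum(axis=-1), 1.0, atol=1e-10)
        assert np.all(np.diff(trace.occupancy[..., S.DEATH]) >= -1e-15)
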