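import numpy as np
import pytest

from bdscreen import (
    ModelParams,
    apply_overrides,
    closed_form_no_screening_cost,
    run_no_screening,
    run_screening,
    simulate_microcohort,
)
from bdscreen.params import round_half_up

from conftest import random_valid_params


class TestNoScreeningBaseCase:
    def test_printed_headline_numbers(self, base_params):
        traj = run_no_screening(base_params)
        assert round_half_up(traj.per_patient_cost) == 50_936
        assert round(traj.total_discounted_cost / 1e6, 1) == 764.0
        assert round_half_up(traj.survivors_end) == 9_582
        assert round_half_up(traj.misdiagnosed_end) == 680
        assert round_half_up(traj.correct_end) == 8_901

    def test_homogeneous_cohort(self):
        # p=0, no attrition, no discounting: everyone costs T x c_mdd
        params = ModelParams.model_validate({
            "epi": {"ubp_prevalence": 0.0, "attrition": 0.0},
            "costs": {"c_mdd": 1_000, "discount": 0.0},
        })
        traj = run_no_screening(params)
        assert traj.per_patient_cost == pytest.approx(5 * 1_000, rel=1e-12)

    def test_no_correction_closed_form_misdiagnoses(self, base_params):
        params = apply_overrides(base_params, {"epi.annual_correction": 0.0})
        traj = run_no_screening(params)
        expected = 15_000 * 0.16 * (1 - 0.106) ** 4
        assert traj.misdiagnosed_end == pytest.approx(expected, rel=1e-12)
        assert round_half_up(expected) == 1_533

    def test_year_records_satisfy_invariants(self, base_params):
        traj = run_no_screening(base_params)
        n0 = base_params.epi.cohort_size
        a = base_params.epi.attrition
        for y in traj.years:
            assert y.mdd + y.rbp + y.ubp + y.mdd_as_bd == pytest.approx(y.n_alive, rel=1e-9)
            assert y.n_alive == pytest.approx(n0 * (1 - a) ** (y.year - 1), rel=1e-12)
            assert y.discounted_cost == pytest.approx(
                y.undiscounted_cost * y.discount_factor, rel=1e-12)
        assert traj.total_discounted_cost == pytest.approx(
            traj.one_time_cost + sum(y.discounted_cost for y in traj.years), rel=1e-12)
        per_patient_states = sum(traj.cost_by_state.values())
        assert per_patient_states == pytest.approx(
            traj.per_patient_cost - traj.one_time_cost / n0, rel=1e-9)


class TestClosedFormOracle:
    def test_base_case_value(self, base_params):
        assert closed_form_no_screening_cost(base_params) == pytest.approx(
            50_935.85, abs=0.01)

    def test_matches_engine_on_random_parameters(self):
        rng = np.random.default_rng(2024)
        for _ in range(1_000):
            params = random_valid_params(rng)
            engine = run_no_screening(params).per_patient_cost
            analytic = closed_form_no_screening_cost(params)
            assert engine == pytest.approx(analytic, rel=1e-9)

    def test_immediate_correction_limit(self):
        # q=1: all UBP corrected in year 1 already
        params = ModelParams.model_validate({
            "epi": {"annual_correction": 1.0, "attrition": 0.0},
            "costs": {"discount": 0.0},
        })
        traj = run_no_screening(params)
        c = params.costs
        p = params.epi.ubp_prevalence
        expected = 5 * ((1 - p) * c.c_mdd + p * c.c_rbp)
        assert traj.per_patient_cost == pytest.approx(expected, rel=1e-12)
        assert closed_form_no_screening_cost(params) == pytest.approx(expected, rel=1e-12)


class TestMonotonicity:
    def test_cost_increases_with_prevalence(self, base_params):
        costs = [run_no_screening(apply_overrides(base_params, {"epi.ubp_prevalence": p}))
                 .per_patient_cost for p in (0.05, 0.11, 0.16, 0.21, 0.4)]
        assert np.all(np.diff(costs) > 0)

    def test_cost_increases_with_ubp_cost(self, base_params):
        costs = [run_no_screening(apply_overrides(base_params, {"costs.c_ubp": c}))
                 .per_patient_cost for c in (18_000, 23_696, 30_000, 40_000)]
        assert np.all(np.diff(costs) > 0)

    def test_cost_decreases_with_correction_rate(self, base_params):
        costs = [run_no_screening(apply_overrides(base_params, {"epi.annual_correction": q}))
                 .per_patient_cost for q in (0.05, 0.15, 0.3, 0.6)]
        assert np.all(np.diff(costs) < 0)


class TestScreeningScenario:
    def test_perfect_screen_with_full_referral(self, base_params):
        params = apply_overrides(base_params, {"epi.referral_prob": 1.0})
        traj = run_screening(params, 1.0, 1.0)
        assert traj.misdiagnosed_end == pytest.approx(0.0, abs=1e-9)

    def test_inert_screen_equals_no_screening(self, base_params):
        params = apply_overrides(base_params, {"costs.c_screen": 0})
        screened = run_screening(params, 0.0, 1.0)
        reference = run_no_screening(params)
        assert screened.total_discounted_cost == pytest.approx(
            reference.total_discounted_cost, rel=1e-12)
        for ys, yr in zip(screened.years, reference.years):
            assert (ys.mdd, ys.rbp, ys.ubp, ys.mdd_as_bd) == pytest.approx(
                (yr.mdd, yr.rbp, yr.ubp, yr.mdd_as_bd), rel=1e-12)

    def test_base_operating_point_figures(self, base_params):
        # hand chain: (312 + 598.5) x 0.85^5 x 0.894^4 misdiagnosed at year 5
        traj = run_screening(base_params, 0.87, 0.81)
        expected_mis = 910.5 * 0.85**5 * 0.894**4
        assert traj.misdiagnosed_end == pytest.approx(expected_mis, rel=1e-12)
        assert round_half_up(traj.misdiagnosed_end) == 258
        assert round_half_up(traj.per_patient_cost) == 49_528

    def test_screening_dominates_without_onetime_costs(self, base_params):
        # with perfect specificity and free screening, any sensitivity helps
        rng = np.random.default_rng(7)
        for _ in range(50):
            params = apply_overrides(base_params, {
                "costs.c_screen": 0, "costs.c_eval": 0,
                "epi.ubp_prevalence": float(rng.uniform(0.05, 0.4)),
            })
            sens = float(rng.uniform(0.05, 1.0))
            assert (run_screening(params, sens, 1.0).total_discounted_cost
                    <= run_no_screening(params).total_discounted_cost + 1e-6)


class TestMicrosimulation:
    def test_same_seed_is_bit_identical(self, base_params):
        a = simulate_microcohort(base_params, 0.87, 0.81, 5_000, seed=11)
        b = simulate_microcohort(base_params, 0.87, 0.81, 5_000, seed=11)
        assert a == b

    @pytest.mark.parametrize("op", [None, (0.87, 0.81)])
    def test_agrees_with_deterministic_engine(self, base_params, op):
        sens, spec = op if op else (None, None)
        micro, costs = simulate_microcohort(base_params, sens, spec, 200_000,
                                            seed=13, return_patient_costs=True)
        se = costs.std() / np.sqrt(len(costs))
        if op is None:
            expected = run_no_screening(base_params).per_patient_cost
        else:
            expected = run_screening(base_params, sens, spec).per_patient_cost
        assert abs(micro.per_patient_cost - expected) < 3 * se

    def test_static_cohort_matches_binomial_expectation(self, base_params):
        # q=0, a=0: misdiagnosed count is frozen at the initial draw
        params = apply_overrides(base_params, {"epi.annual_correction": 0.0,
                                               "epi.attrition": 0.0})
        n = 50_000
        micro = simulate_microcohort(params, None, None, n, seed=5)
        assert micro.misdiagnosed_end == micro.years[0].ubp
        p = params.epi.ubp_prevalence
        se = np.sqrt(n * p * (1 - p))
        assert abs(micro.misdiagnosed_end - n * p) < 3 * se

    def test_invalid_arguments(self, base_params):
        with pytest.raises(ValueError):
            simulate_microcohort(base_params, 0.9, None, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_microcohort(base_params, None, None, 0, seed=0)


def test_all_valid_parameters_yield_finite_outputs():
    rng = np.random.default_rng(99)
    for _ in range(100):
        params = random_valid_params(rng)
        traj = run_no_screening(params)
        assert np.isfinite(traj.total_discounted_cost)
        screened = run_screening(params, float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
        assert np.isfinite(screened.total_discounted_cost)
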