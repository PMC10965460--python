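"""Illness-death transition probabilities, panel likelihood and life
expectancy, checked against independent ODE and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from halex import (GompertzIntensities, build_intensity_matrix,
                   life_expectancy_ci, panel_log_likelihood,
                   state_specific_life_expectancy, transition_probability)

from conftest import make_records


def ode_transition_matrix(model, a0, a1, z=None):
    """Independent oracle: Kolmogorov forward equations P' = P Q(a) solved
    with a high-accuracy adaptive ODE integrator."""
    def rhs(a, p):
        return (p.reshape(3, 3) @ model.intensity_matrix(a, z)).ravel()
    sol = solve_ivp(rhs, (a0, a1), np.eye(3).ravel(), rtol=1e-11, atol=1e-13,
                    dense_output=True)
    return sol.y[:, -1].reshape(3, 3)


def random_models(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        constant = rng.random() < 0.5
        out.append(GompertzIntensities(
            alpha=np.log(rng.uniform(0.005, 0.08, size=3)),
            xi=np.zeros(3) if constant else rng.uniform(-0.02, 0.12, size=3),
            beta=np.zeros((3, 0)), covariate_names=()))
    return out


class TestGenerator:
    def test_row_sums_and_absorbing_state(self, gompertz_model):
        Q = build_intensity_matrix(gompertz_model, 72.0, [1.0])
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(Q[2], 0.0)
        assert Q[1, 0] == 0.0 and Q[2, 0] == 0.0 and Q[2, 1] == 0.0

    def test_constant_model_diagonal(self, constant_model):
        Q = build_intensity_matrix(constant_model, 65.0)
        assert np.allclose(np.diag(Q), [-0.05, -0.05, 0.0])
        assert Q[0, 1] == pytest.approx(0.03) and Q[0, 2] == pytest.approx(0.02)

    def test_zero_intensity_limit(self):
        m = GompertzIntensities.constant(0.0, 0.0, 0.0)
        assert np.allclose(build_intensity_matrix(m, 70.0), 0.0)

    def test_log_linear_age_slope(self):
        m = GompertzIntensities(alpha=[np.log(0.03), np.log(0.02), np.log(0.05)],
                                xi=[0.1, 0.0, 0.0], beta=np.zeros((3, 0)),
                                covariate_names=())
        q_ref = build_intensity_matrix(m, 65.0)[0, 1]
        q_10 = build_intensity_matrix(m, 75.0)[0, 1]
        assert q_10 == pytest.approx(np.e * q_ref, rel=1e-12)


class TestTransitionProbability:
    def test_zero_interval_is_identity(self, gompertz_model):
        P = transition_probability(gompertz_model, 70.0, 70.0, [0.0])
        assert np.allclose(P, np.eye(3))

    def test_pure_death_closed_form(self):
        m = GompertzIntensities.constant(0.0, 0.04, 0.0)
        P = transition_probability(m, 65.0, 75.0)
        assert P[0, 0] == pytest.approx(np.exp(-0.4), rel=1e-12)
        assert P[0, 1] == 0.0

    def test_constant_model_matches_ode_oracle(self, constant_model):
        P = transition_probability(constant_model, 65.0, 75.0)
        P_ode = ode_transition_matrix(constant_model, 65.0, 75.0)
        assert np.abs(P - P_ode).max() < 1e-8

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_generators_match_ode_oracle(self, seed):
        for model in random_models(4, seed):
            P = transition_probability(model, 65.0, 73.0, grid_step=0.004)
            P_ode = ode_transition_matrix(model, 65.0, 73.0)
            assert np.abs(P - P_ode).max() < 1e-8

    def test_eigenvalue_collision_is_stable(self):
        # q12 + q13 == q23 collapses the eigenvalue gap to zero exactly
        m = GompertzIntensities.constant(0.03, 0.02, 0.05)
        P = transition_probability(m, 65.0, 80.0)
        P_ode = ode_transition_matrix(m, 65.0, 80.0)
        assert np.abs(P - P_ode).max() < 1e-10

    def test_stochastic_matrix_invariants(self, gompertz_model):
        for z in ([0.0], [1.0]):
            P = transition_probability(gompertz_model, 65.0, 90.0, z)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-8)
            assert np.all((P >= 0) & (P <= 1))
            assert P[2, 2] == 1.0 and P[1, 0] == 0.0

    def test_chapman_kolmogorov_for_constant_model(self, constant_model):
        P02 = transition_probability(constant_model, 65.0, 81.0)
        P01 = transition_probability(constant_model, 65.0, 72.0)
        P12 = transition_probability(constant_model, 72.0, 81.0)
        assert np.abs(P02 - P01 @ P12).max() < 1e-8

    def test_reversed_ages_rejected(self, constant_model):
        with pytest.raises(ValueError):
            transition_probability(constant_model, 70.0, 65.0)


class TestPanelLikelihood:
    def test_single_survivor_matches_closed_form(self, constant_model):
        rec = make_records([(0, "female", 65.0, 1, 72.0, "alive_observed", 1)])
        ll = panel_log_likelihood(constant_model, rec)
        assert ll == pytest.approx(np.log(np.exp(-0.05 * 7.0)), rel=1e-10)

    def test_exact_death_sums_over_predeath_states(self, constant_model):
        rec = make_records([(0, "female", 65.0, 1, 70.0, "death_exact", None)])
        P = ode_transition_matrix(constant_model, 65.0, 70.0)
        expected = np.log(P[0, 0] * 0.02 + P[0, 1] * 0.05)
        assert panel_log_likelihood(constant_model, rec) == pytest.approx(
            expected, abs=1e-6)

    def test_brute_force_oracle_on_mixed_records(self, gompertz_model):
        rec = make_records([
            (0, "female", 66.0, 1, 69.5, "alive_observed", 1),
            (1, "male", 70.0, 1, 73.0, "alive_observed", 2),
            (2, "female", 72.0, 2, 74.5, "alive_observed", 2),
            (3, "male", 67.0, 1, 68.2, "death_exact", None),
            (4, "female", 75.0, 2, 77.1, "death_exact", None),
        ])
        expected = 0.0
        for _, r in rec.iterrows():
            z = [1.0] if r["sex"] == "male" else [0.0]
            P = ode_transition_matrix(gompertz_model, r["entry_age"], r["exit_age"], z)
            s0 = int(r["entry_state"]) - 1
            if r["exit_kind"] == "alive_observed":
                expected += np.log(P[s0, int(r["exit_state"]) - 1])
            else:
                q = gompertz_model.rates(r["exit_age"], np.array(z))
                expected += np.log(P[s0, 0] * q[1] + P[s0, 1] * q[2])
        got = panel_log_likelihood(gompertz_model, rec, grid_step=0.02)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_recovery_observation_is_impossible(self, constant_model):
        rec = make_records([(7, "male", 65.0, 2, 68.0, "alive_observed", 1)])
        with pytest.warns(RuntimeWarning, match="zero-probability"):
            ll = panel_log_likelihood(constant_model, rec)
        assert np.isneginf(ll)

    def test_lost_records_contribute_nothing(self, constant_model):
        rec = make_records([
            (0, "female", 65.0, 1, 70.0, "alive_observed", 1),
            (1, "female", 65.0, 1, 68.0, "lost", None),
        ])
        only = make_records([(0, "female", 65.0, 1, 70.0, "alive_observed", 1)])
        assert panel_log_likelihood(constant_model, rec) == pytest.approx(
            panel_log_likelihood(constant_model, only))

    def test_truth_beats_perturbed_parameters(self, gompertz_model, small_cohort):
        ll_true = panel_log_likelihood(gompertz_model, small_cohort)
        for j in range(3):
            alpha = gompertz_model.alpha.copy()
            alpha[j] += np.log(1.5)
            worse = GompertzIntensities(alpha=alpha, xi=gompertz_model.xi,
                                        beta=gompertz_model.beta,
                                        reference_age=gompertz_model.reference_age,
                                        covariate_names=gompertz_model.covariate_names)
            assert panel_log_likelihood(worse, small_cohort) < ll_true


class TestLifeExpectancy:
    def test_constant_intensity_closed_form(self):
        # e11 = 1/(q12+q13); e12 = q12/((q12+q13) q23)
        m = GompertzIntensities.constant(0.02, 0.05, 0.10)
        le = state_specific_life_expectancy(m, 65.0, grid_step=0.1, max_age=65.0 + 400)
        assert le.years_in_state[1] == pytest.approx(1 / 0.07, abs=1e-3)
        assert le.years_in_state[2] == pytest.approx(0.02 / (0.07 * 0.10), abs=1e-3)
        assert le.total == pytest.approx(1 / 0.07 + 0.02 / (0.07 * 0.10), abs=2e-3)

    def test_no_onset_means_no_diseased_years(self):
        m = GompertzIntensities.constant(0.0, 0.05, 0.10)
        le = state_specific_life_expectancy(m, 65.0, max_age=65.0 + 400)
        assert le.years_in_state[2] == 0.0
        assert le.total == pytest.approx(1 / 0.05, abs=1e-3)

    def test_start_in_disease_state_is_single_exponential(self):
        m = GompertzIntensities.constant(0.02, 0.05, 0.10)
        le = state_specific_life_expectancy(m, 65.0, start_state=2, max_age=65.0 + 400)
        assert le.years_in_state[1] == 0.0
        assert le.total == pytest.approx(1 / 0.10, abs=1e-3)

    def test_grid_halving_changes_little(self, gompertz_model):
        a = state_specific_life_expectancy(gompertz_model, 65.0, z=[0.0], grid_step=0.1)
        b = state_specific_life_expectancy(gompertz_model, 65.0, z=[0.0], grid_step=0.05)
        assert abs(a.total - b.total) < 1e-3
        assert abs(a.years_in_state[1] - b.years_in_state[1]) < 1e-3

    def test_truncation_warning_when_mass_remains(self):
        m = GompertzIntensities.constant(0.001, 0.001, 0.001)
        with pytest.warns(RuntimeWarning, match="survival mass"):
            le = state_specific_life_expectancy(m, 65.0, max_age=80.0)
        assert le.residual_mass > 1e-3


class TestLifeExpectancyCI:
    def test_zero_covariance_degenerates_to_point(self, gompertz_model):
        k = gompertz_model.to_vector().size
        ci = life_expectancy_ci(gompertz_model, np.zeros((k, k)), 65.0, z=[0.0],
                                n_draws=50, seed=3)
        point = state_specific_life_expectancy(gompertz_model, 65.0, z=[0.0])
        assert ci.loc["total", "ci_low"] == pytest.approx(point.total, rel=1e-9)
        assert ci.loc["total", "ci_high"] == pytest.approx(point.total, rel=1e-9)

    def test_fixed_seed_reproducible(self, gompertz_model):
        k = gompertz_model.to_vector().size
        cov = 0.01 * np.eye(k)
        a = life_expectancy_ci(gompertz_model, cov, 65.0, z=[1.0], n_draws=100, seed=9)
        b = life_expectancy_ci(gompertz_model, cov, 65.0, z=[1.0], n_draws=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_indefinite_covariance_rejected(self, gompertz_model):
        k = gompertz_model.to_vector().size
        cov = -0.1 * np.eye(k)
        with pytest.raises(ValueError, match="positive semi-definite"):
            life_expectancy_ci(gompertz_model, cov, 65.0, z=[0.0], n_draws=10)
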