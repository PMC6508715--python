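import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastropd.response import (
    ClinicalResponseModel,
    ResponseParams,
    category_probabilities,
    cumulative_logit,
    logistic,
    marginal_loglik,
    simulate_trajectory,
    trajectory_loglik_conditional,
    transition_matrix,
)
from gastropd.simulate import SimulationConfig, simulate_cohort


class TestCumulativeLogit:
    def test_baseline_logit_is_beta1(self, table_response_params):
        assert cumulative_logit(table_response_params, 1) == pytest.approx(19.7)

    def test_threshold_two_is_partial_sum(self, table_response_params):
        assert cumulative_logit(table_response_params, 2) == pytest.approx(15.08)

    def test_markov_effect_subtracted(self, table_response_params):
        # previous stable disease: 19.7 - 19.4
        L = cumulative_logit(table_response_params, 1, prev_state=1)
        assert L == pytest.approx(0.3)

    def test_unknown_covariate_rejected(self, table_response_params):
        with pytest.raises(KeyError):
            cumulative_logit(table_response_params, 1, covariates={"BOGUS": 1.0})

    def test_invalid_threshold_rejected(self, table_response_params):
        with pytest.raises(ValueError):
            cumulative_logit(table_response_params, 3)


class TestLogistic:
    def test_symmetry_at_zero(self):
        assert logistic(0.0) == 0.5

    def test_diagnosis_logit_saturates(self):
        assert logistic(19.7) == pytest.approx(1 - 2.8e-9, abs=1e-10)

    def test_negative_logit(self):
        assert logistic(-4.62) == pytest.approx(0.0097567, abs=1e-6)

    def test_overflow_safe(self):
        assert logistic(700.0) == 1.0
        assert logistic(-700.0) == pytest.approx(0.0, abs=1e-300)


class TestCategoryProbabilities:
    def test_all_mass_on_progression_at_diagnosis(self, table_response_params):
        p = category_probabilities(table_response_params)
        assert p[2] == pytest.approx(1.0, abs=1e-6)
        assert p.sum() == pytest.approx(1.0)

    def test_zero_logits_split(self):
        # both cumulative probabilities are 1/2, so the middle category is empty
        p = category_probabilities(ResponseParams(beta=(0.0, 0.0)))
        assert np.allclose(p, [0.5, 0.0, 0.5])
        # a genuinely three-way split needs beta2 < 0
        p2 = category_probabilities(ResponseParams(beta=(0.0, -math.log(3))))
        assert np.allclose(p2, [0.5, 0.25, 0.25])

    @given(
        b1=st.floats(-30, 30), b2=st.floats(-30, 0),
        th=st.floats(-25, 25), eta=st.floats(-10, 10),
        prev=st.sampled_from([None, 0, 1, 2]),
    )
    @settings(max_examples=200, deadline=None)
    def test_valid_probability_vector_always(self, b1, b2, th, eta, prev):
        params = ResponseParams(beta=(b1, b2),
                                theta_markov={"PR": th, "SD": th, "DP": th})
        p = category_probabilities(params, prev_state=prev, eta=eta)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0)

    def test_non_monotone_cumulative_rejected(self):
        with pytest.raises(ValueError):
            category_probabilities(ResponseParams(beta=(0.0, 2.0)))


class TestTransitionMatrix:
    def test_rows_stochastic(self, table_response_params):
        T = transition_matrix(table_response_params)
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_stable_disease_row_partial_response(self, table_response_params):
        # L1 = 0.3, L2 = 0.3 - 4.62 under the subtraction convention
        T = transition_matrix(table_response_params)
        assert T[1, 0] == pytest.approx(1 - logistic(0.3), abs=1e-12)
        assert T[1, 0] == pytest.approx(0.4256, abs=5e-4)

    def test_equal_markov_effects_give_identical_rows(self):
        params = ResponseParams(beta=(1.0, -1.0),
                                theta_markov={"PR": 2.0, "SD": 2.0, "DP": 2.0})
        T = transition_matrix(params)
        assert np.allclose(T[0], T[1]) and np.allclose(T[1], T[2])

    def test_markov_monotonicity(self):
        # larger theta_SD lowers P(Y>=1 | prev SD) under the sign convention
        def p_ge1(theta_sd):
            params = ResponseParams(beta=(2.0, -1.0),
                                    theta_markov={"PR": 0, "SD": theta_sd, "DP": 0})
            return 1.0 - category_probabilities(params, prev_state=1)[0]

        vals = [p_ge1(t) for t in (0.0, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestTrajectoryLoglik:
    def test_single_diagnosis_visit_near_certain(self, table_response_params):
        ll = trajectory_loglik_conditional(table_response_params, [2])
        assert ll == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("length", [2, 3, 4])
    def test_probabilities_normalize_by_enumeration(self, table_response_params, length):
        total = 0.0
        for cont in itertools.product((0, 1, 2), repeat=length - 1):
            seq = [2, *cont]
            total += math.exp(
                trajectory_loglik_conditional(table_response_params, seq, eta=0.3)
            )
        # sums to P(first visit = 2), which is 1 up to ~3e-9 at these estimates
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_full_enumeration_exactly_one(self):
        # enumerating the first category too gives exactly 1 for any params
        params = ResponseParams(beta=(0.7, -1.1),
                                theta_markov={"PR": 0.5, "SD": -0.2, "DP": 1.0})
        total = sum(
            math.exp(trajectory_loglik_conditional(params, list(seq), eta=-0.8))
            for seq in itertools.product((0, 1, 2), repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_impossible_observation_gives_minus_inf(self):
        params = ResponseParams(beta=(700.0, -0.1))  # category 0 impossible
        ll = trajectory_loglik_conditional(params, [2, 0])
        assert ll == -math.inf

    def test_missing_interior_observation_skipped(self, table_response_params):
        full = trajectory_loglik_conditional(table_response_params, [2, 1, 0])
        gap = trajectory_loglik_conditional(table_response_params, [2, None, 0])
        assert gap != full
        assert np.isfinite(gap)


class TestMarginalLoglik:
    def test_zero_variance_equals_conditional(self, small_cohort, table_response_params):
        from dataclasses import replace

        p0 = replace(table_response_params, omega2=0.0)
        ll0 = marginal_loglik(p0, small_cohort, method="laplace")
        # manual conditional sum at eta = 0
        total = 0.0
        for _, g in small_cohort.visits.groupby("patient_id"):
            seq = [int(x) for x in g["response_dv"]]
            total += trajectory_loglik_conditional(p0, seq, eta=0.0)
        assert ll0 == pytest.approx(total, abs=1e-10)

    def test_laplace_approaches_conditional_as_variance_vanishes(
        self, small_cohort, table_response_params
    ):
        from dataclasses import replace

        p_small = replace(table_response_params, omega2=1e-10)
        p_zero = replace(table_response_params, omega2=0.0)
        lap = marginal_loglik(p_small, small_cohort, method="laplace")
        cond = marginal_loglik(p_zero, small_cohort, method="laplace")
        assert lap == pytest.approx(cond, abs=1e-6)

    def test_laplace_tracks_quadrature_at_moderate_variance(
        self, small_cohort, table_response_params
    ):
        # at omega2 = 1 the one-term Laplace expansion carries a genuine
        # truncation error of order 1e-2 for 4-visit subjects
        lap = marginal_loglik(table_response_params, small_cohort, method="laplace")
        agq = marginal_loglik(
            table_response_params, small_cohort, method="quadrature", n_nodes=64
        )
        assert lap == pytest.approx(agq, abs=0.05)

    def test_quadrature_matches_dense_quadrature(self, small_cohort, table_response_params):
        a21 = marginal_loglik(table_response_params, small_cohort,
                              method="quadrature", n_nodes=21)
        a64 = marginal_loglik(table_response_params, small_cohort,
                              method="quadrature", n_nodes=64)
        assert a21 == pytest.approx(a64, abs=1e-8)

    def test_montecarlo_requires_seed(self, small_cohort, table_response_params):
        with pytest.raises(ValueError):
            marginal_loglik(table_response_params, small_cohort, method="montecarlo")


class TestFit:
    def test_all_fixed_returns_ofv_at_init(self, small_cohort, table_response_params):
        model = ClinicalResponseModel(small_cohort)
        res = model.fit(init=table_response_params, free=[])
        assert res.converged
        assert res.ofv == pytest.approx(-2.0 * model.loglik(table_response_params))
        assert res.n_function_evals <= 1

    def test_fit_not_worse_than_truth(self, table_response_params):
        cohort = simulate_cohort(SimulationConfig(n_patients=150, seed=3))
        model = ClinicalResponseModel(cohort)
        res = model.fit(
            init=table_response_params,
            free=["beta2", "theta_pr", "theta_sd", "theta_dp", "omega2"],
            compute_covariance=False,
        )
        assert res.ofv <= -2.0 * model.loglik(table_response_params) + 1e-6

    def test_unknown_free_name_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            ClinicalResponseModel(small_cohort).fit(free=["nonsense"])

    def test_report_csv_round_trip(self, table_response_params, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_patients=60, seed=4))
        res = ClinicalResponseModel(cohort).fit(
            init=table_response_params, free=["beta2", "omega2"]
        )
        res.to_report_csv(tmp_path / "fit.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "fit.csv")
        assert set(back["parameter"]) == {"beta2", "omega2"}
        assert {"estimate", "se", "rse_percent", "lower95", "upper95"} <= set(back)


class TestSimulateTrajectory:
    def test_single_visit_always_progression(self, table_response_params):
        rng = np.random.default_rng(0)
        assert all(
            simulate_trajectory(table_response_params, n_visits=1, rng=rng) == [2]
            for _ in range(50)
        )

    def test_same_seed_reproduces(self, table_response_params):
        a = simulate_trajectory(table_response_params, n_visits=4,
                                rng=np.random.default_rng(5))
        b = simulate_trajectory(table_response_params, n_visits=4,
                                rng=np.random.default_rng(5))
        assert a == b

    def test_second_visit_frequencies_match_probabilities(self, table_response_params):
        rng = np.random.default_rng(8)
        n = 100_000
        draws = np.array(
            [simulate_trajectory(table_response_params, n_visits=2, rng=rng, eta=0.0)[1]
             for _ in range(0)]
        )
        # vectorized path for speed
        from gastropd.response import _simulate_dv_matrix

        dv = _simulate_dv_matrix(table_response_params, n, 2, rng,
                                 eta=np.zeros(n))
        freq = np.bincount(dv[:, 1], minlength=3) / n
        expected = category_probabilities(table_response_params, prev_state=2)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) <= 3 * se + 1e-12)

    def test_invalid_visit_count(self, table_response_params):
        with pytest.raises(ValueError):
            simulate_trajectory(table_response_params, n_visits=5)
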