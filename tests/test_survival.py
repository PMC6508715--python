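import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gastropd.survival import (
    HazardParams,
    ParametricSurvivalModel,
    cumulative_hazard,
    cumulative_hazard_quad,
    event_loglik,
    hazard_at,
    hazard_ratio,
    kaplan_meier,
    km_at,
    simulate_event_time,
    survival_frame,
    survival_prob,
)
from gastropd.simulate import SimulationConfig, simulate_cohort


class TestHazardAt:
    def test_baseline_rate(self, table_os_params):
        assert hazard_at(table_os_params, 100.0) == pytest.approx(1e-4)

    def test_linitis_increment_additive(self, table_os_params):
        assert hazard_at(table_os_params, 100.0, linitis=True) == pytest.approx(3e-4)

    def test_metastasis_multiplies_hazard(self, table_os_params):
        h = hazard_at(table_os_params, 1500.0, t_met=1000.0)
        assert h == pytest.approx(1e-4 * math.exp(3.43), rel=1e-12)
        assert h == pytest.approx(3.088e-3, abs=2e-6)

    def test_before_metastasis_unchanged(self, table_os_params):
        assert hazard_at(table_os_params, 500.0, t_met=1000.0) == pytest.approx(1e-4)

    def test_negative_composite_rate_rejected(self):
        p = HazardParams(lambda0=1e-4, delta_stage=-2e-4)
        with pytest.raises(ValueError):
            hazard_at(p, 10.0, stage3=True)


class TestCumulativeHazard:
    def test_zero_at_origin(self, table_os_params):
        assert cumulative_hazard(table_os_params, 0.0) == 0.0

    def test_eight_year_constant(self, table_os_params):
        assert cumulative_hazard(table_os_params, 2920.0) == pytest.approx(0.292)

    def test_piecewise_metastasis_switch(self, table_os_params):
        hz = cumulative_hazard(table_os_params, 2000.0, t_met=1000.0)
        expected = 0.1 + 0.1 * math.exp(3.43)
        assert hz == pytest.approx(expected, rel=1e-12)
        assert hz == pytest.approx(3.188, abs=2e-3)

    @pytest.mark.parametrize(
        "params",
        [
            HazardParams(family="constant", lambda0=3e-4),
            HazardParams(family="weibull", lambda0=1e-5, shape=1.4),
            HazardParams(family="gompertz", lambda0=8e-5, shape=4e-4),
        ],
        ids=["constant", "weibull", "gompertz"],
    )
    def test_closed_form_matches_quadrature(self, params):
        for t, tm in ((500.0, None), (2500.0, 900.0)):
            p = params if tm is None else HazardParams(
                **{**params.__dict__, "beta_met": 1.2}
            )
            closed = cumulative_hazard(p, t, t_met=tm)
            numeric = cumulative_hazard_quad(p, t, t_met=tm)
            assert closed == pytest.approx(numeric, abs=1e-8)

    @given(
        t1=st.floats(0, 4000), t2=st.floats(0, 4000),
        lam=st.floats(1e-5, 1e-3), bm=st.floats(-1, 4),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing(self, t1, t2, lam, bm):
        p = HazardParams(lambda0=lam, beta_met=bm)
        lo, hi = sorted((t1, t2))
        assert cumulative_hazard(p, lo, t_met=800.0) <= cumulative_hazard(
            p, hi, t_met=800.0
        ) + 1e-12


class TestSurvivalProb:
    def test_starts_at_one(self, table_os_params):
        assert survival_prob(table_os_params, 0.0) == 1.0

    def test_eight_year_value(self, table_os_params):
        assert survival_prob(table_os_params, 2920.0) == pytest.approx(
            math.exp(-0.292)
        )
        assert survival_prob(table_os_params, 2920.0) == pytest.approx(0.747, abs=5e-4)

    def test_non_increasing(self, table_os_params):
        t = np.linspace(0, 4000, 50)
        s = survival_prob(table_os_params, t, stage3=True, linitis=True, t_met=700.0)
        assert np.all(np.diff(s) <= 1e-15)


class TestEventLoglik:
    def test_single_subject_closed_form(self):
        lam, t = 2e-4, 800.0
        data = pd.DataFrame({"time_days": [t], "observed": [True]})
        ll = event_loglik(HazardParams(lambda0=lam), data)
        assert ll == pytest.approx(math.log(lam) - lam * t)

    def test_mle_is_inverse_time_for_one_event(self):
        t = 640.0
        data = pd.DataFrame({"time_days": [t], "observed": [True]})
        lams = np.linspace(0.5 / t, 2.0 / t, 101)
        lls = [event_loglik(HazardParams(lambda0=l), data) for l in lams]
        assert lams[int(np.argmax(lls))] == pytest.approx(1.0 / t, rel=0.02)

    def test_all_censored_decreasing_in_rate(self):
        data = pd.DataFrame({"time_days": [100.0, 300.0], "observed": [False, False]})
        ll1 = event_loglik(HazardParams(lambda0=1e-4), data)
        ll2 = event_loglik(HazardParams(lambda0=5e-4), data)
        assert ll1 == pytest.approx(-1e-4 * 400.0)
        assert ll2 < ll1

    def test_nonpositive_time_rejected(self):
        data = pd.DataFrame({"time_days": [0.0], "observed": [True]})
        with pytest.raises(ValueError):
            event_loglik(HazardParams(lambda0=1e-4), data)

    def test_constant_mle_equals_deaths_over_persontime(self):
        rng = np.random.default_rng(12)
        n, lam = 500, 3e-4
        t = rng.exponential(1.0 / lam, n)
        cens = np.full(n, 2000.0)
        obs = t < cens
        tt = np.minimum(t, cens)
        data = pd.DataFrame({"time_days": tt, "observed": obs})
        closed = obs.sum() / tt.sum()
        fit = ParametricSurvivalModel(data, family="constant").fit(
            init=HazardParams(lambda0=1e-4), free=["lambda0"],
            compute_covariance=False,
        )
        assert fit.estimates.lambda0 == pytest.approx(closed, rel=1e-6)


class TestFitSurvivalModel:
    def test_fit_not_worse_than_truth(self, table_os_params):
        cohort = simulate_cohort(SimulationConfig(n_patients=300, seed=21))
        model = ParametricSurvivalModel(cohort, family="constant")
        fit = model.fit(init=table_os_params,
                        free=["lambda0", "delta_stage", "delta_linitis", "beta_met"],
                        compute_covariance=False)
        assert fit.converged
        assert fit.ofv <= model.ofv(table_os_params) + 1e-6

    def test_no_events_rejected(self):
        data = pd.DataFrame({"time_days": [100.0, 200.0], "observed": [False, False]})
        with pytest.raises(ValueError):
            ParametricSurvivalModel(data).fit()

    def test_survival_frame_extraction(self, three_patient_cohort):
        df = survival_frame(three_patient_cohort)
        assert len(df) == 2  # P1 death observed, P2 censored; P3 has no death row
        p1 = df.set_index("patient_id").loc["P1"]
        assert p1["observed"] and p1["t_met"] == 300.0


class TestHazardRatio:
    def test_metastasis_ratio(self, table_os_params):
        assert hazard_ratio(table_os_params, "metastasis") == pytest.approx(
            math.exp(3.43)
        )
        assert hazard_ratio(table_os_params, "metastasis") == pytest.approx(30.9, abs=0.05)

    def test_linitis_ratio(self, table_os_params):
        assert hazard_ratio(table_os_params, "linitis") == pytest.approx(3.0)

    def test_null_increment_gives_unity(self):
        assert hazard_ratio(HazardParams(lambda0=1e-4), "stage3") == 1.0


class TestSimulateEventTime:
    def test_exponential_distribution_ks(self):
        lam = 4e-4
        rng = np.random.default_rng(33)
        p = HazardParams(lambda0=lam)
        times = np.array(
            [simulate_event_time(p, rng=rng)[0] for _ in range(10_000)]
        )
        from scipy.stats import kstest

        stat = kstest(times, "expon", args=(0, 1.0 / lam))
        assert stat.pvalue > 0.01

    def test_zero_follow_up_censors_immediately(self, table_os_params):
        t, obs = simulate_event_time(table_os_params, max_follow_days=0.0,
                                     rng=np.random.default_rng(0))
        assert t == 0.0 and not obs

    def test_same_seed_same_time(self, table_os_params):
        a = simulate_event_time(table_os_params, rng=np.random.default_rng(9))
        b = simulate_event_time(table_os_params, rng=np.random.default_rng(9))
        assert a == b

    def test_weibull_inversion_consistent(self):
        p = HazardParams(family="weibull", lambda0=1e-5, shape=1.5, beta_met=1.0)
        rng = np.random.default_rng(4)
        for _ in range(20):
            t, obs = simulate_event_time(p, t_met=500.0, rng=rng)
            assert obs and t > 0


class TestKaplanMeier:
    def test_hand_computed_example(self):
        times = [1, 2, 3, 3, 4]
        observed = [False, True, True, True, False]
        curve = kaplan_meier(times, observed)
        assert km_at(curve, 2.0) == pytest.approx(0.75)
        assert km_at(curve, 3.0) == pytest.approx(0.25)
        assert km_at(curve, 0.5) == 1.0

    def test_no_censoring_matches_empirical(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(100.0, 200)
        curve = kaplan_meier(t, np.ones(200, bool))
        grid = np.quantile(t, [0.2, 0.5, 0.8])
        emp = [(t > g).mean() for g in grid]
        assert np.allclose(km_at(curve, grid), emp, atol=1e-12)

    def test_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        t = rng.exponential(300.0, 300)
        c = rng.uniform(0, 600.0, 300)
        obs = t < c
        tt = np.minimum(t, c)
        curve = kaplan_meier(tt, obs)
        kmf = lifelines.KaplanMeierFitter().fit(tt, obs)
        grid = np.linspace(10, 500, 20)
        ref = kmf.survival_function_at_times(grid).to_numpy()
        assert np.allclose(km_at(curve, grid), ref, atol=1e-10)

    def test_converges_to_true_exponential_survival(self):
        lam, n = 2e-4, 5000
        rng = np.random.default_rng(8)
        t = rng.exponential(1.0 / lam, n)
        c = rng.uniform(0, 2 / lam, n)
        obs = t < c
        curve = kaplan_meier(np.minimum(t, c), obs)
        grid = np.linspace(50, 4000, 60)
        sup = np.max(np.abs(km_at(curve, grid) - np.exp(-lam * grid)))
        assert sup < 0.03

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])
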