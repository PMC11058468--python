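import numpy as np
import pytest
from scipy import integrate

from arthrocomp import fpm, registry
from arthrocomp.config import SimConfig
from arthrocomp.exceptions import EstimationError
from tests.conftest import simulate_two_arm_exponential


def _exponential_model(rate: float, log_hr: float = 0.0) -> fpm.FPSurvivalModel:
    """Exact exponential-hazard model built directly from coefficients."""
    spec = fpm.SplineSpec(knots=(np.log(1e-3), np.log(20.0)))
    p = np.array([np.log(rate), 1.0, log_hr])
    return fpm.FPSurvivalModel(
        params=p, baseline_spec=spec, tvc_spec=None,
        cov_model=np.eye(3) * 1e-10, cov_robust=np.eye(3) * 1e-10,
        loglik=0.0, converged=True, n=1, n_events=1, time_range=(1e-3, 20.0),
        score_contributions=np.zeros((1, 3)), bread_inv=np.eye(3),
    )


class TestRcsBasis:
    def test_no_interior_knots_reduces_to_linear(self):
        spec = fpm.SplineSpec(knots=(0.0, 1.0))
        b, db = fpm.rcs_basis(np.array([0.3, 0.7]), spec)
        np.testing.assert_allclose(b, [[1, 0.3], [1, 0.7]])
        np.testing.assert_allclose(db, [[0, 1], [0, 1]])

    def test_lambda_weighting_at_midpoint_knot(self):
        # knots (0, 0.5, 1): lambda_1 = (1-0.5)/(1-0) = 0.5
        spec = fpm.SplineSpec(knots=(0.0, 0.5, 1.0))
        x = np.array([0.8])
        b, _ = fpm.rcs_basis(x, spec)
        lam = 0.5
        expected = (0.8 - 0.5) ** 3 - lam * 0.8**3  # (x-kmax)+ = 0
        assert b[0, 2] == pytest.approx(expected)

    def test_linear_beyond_boundary_knots(self):
        spec = fpm.SplineSpec(knots=(-1.0, 0.0, 0.5, 1.0))
        for x0 in (-1.8, 1.9):
            h = 1e-4
            xs = np.array([x0 - h, x0, x0 + h])
            b, _ = fpm.rcs_basis(xs, spec)
            second = (b[0] - 2 * b[1] + b[2]) / h**2
            np.testing.assert_allclose(second, 0.0, atol=1e-5)

    def test_derivative_matches_finite_differences(self):
        spec = fpm.SplineSpec(knots=(-1.0, -0.2, 0.3, 1.0))
        x = np.linspace(-1.5, 1.5, 21)
        h = 1e-6
        b_plus, _ = fpm.rcs_basis(x + h, spec)
        b_minus, _ = fpm.rcs_basis(x - h, spec)
        _, db = fpm.rcs_basis(x, spec)
        np.testing.assert_allclose(db, (b_plus - b_minus) / (2 * h), atol=1e-5)

    def test_invalid_knots_rejected(self):
        with pytest.raises(ValueError):
            fpm.SplineSpec(knots=(1.0, 0.0))


class TestFitFpm:
    def test_exponential_special_case_recovers_weibull_shape_one(self):
        obs, d, arm = simulate_two_arm_exponential(5000, hr=1.0, rate0=1.0, seed=42)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=1, df_tvc=0)
        shape, shape_se = m.params[1], np.sqrt(m.cov_model[1, 1])
        assert abs(shape - 1.0) < 3 * shape_se

    def test_proportional_hazards_recovery(self):
        obs, d, arm = simulate_two_arm_exponential(8000, hr=0.5, rate0=1.0, seed=7)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        beta_se = np.sqrt(m.cov_model[m.n_baseline, m.n_baseline])
        assert abs(m.beta - np.log(0.5)) < 3 * beta_se

    def test_zero_events_is_estimation_error(self):
        with pytest.raises(EstimationError, match="events"):
            fpm.fit_fpm(np.ones(10), np.zeros(10), np.arange(10) % 2)

    def test_nesting_of_time_varying_terms(self):
        obs, d, arm = simulate_two_arm_exponential(3000, hr=0.6, seed=11)
        m0 = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        m2 = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=2)
        assert m2.loglik >= m0.loglik - 1e-6

    def test_weight_splitting_leaves_estimate_unchanged(self):
        obs, d, arm = simulate_two_arm_exponential(1000, hr=0.7, seed=3)
        m1 = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        obs2 = np.repeat(obs, 2)
        d2 = np.repeat(d, 2)
        arm2 = np.repeat(arm, 2)
        m2 = fpm.fit_fpm(obs2, d2, arm2, weights=np.full(2000, 0.5),
                         baseline_spec=m1.baseline_spec, df_tvc=0)
        np.testing.assert_allclose(m1.params, m2.params, atol=1e-5)


class TestRobustCovariance:
    def test_singleton_clusters_equal_conventional_sandwich(self):
        obs, d, arm = simulate_two_arm_exponential(1500, hr=0.8, seed=5)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        conventional = fpm.robust_covariance(m, cluster_ids=None)
        singleton = fpm.robust_covariance(m, cluster_ids=np.arange(1500))
        np.testing.assert_allclose(conventional, singleton, rtol=1e-10)

    def test_cluster_aggregation_changes_variance_not_estimate(self):
        obs, d, arm = simulate_two_arm_exponential(1000, hr=0.8, seed=6)
        pairs = np.repeat(np.arange(500), 2)
        m = fpm.fit_fpm(obs, d, arm, cluster_ids=pairs, df_baseline=2, df_tvc=0)
        m_ind = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        np.testing.assert_allclose(m.params, m_ind.params, atol=1e-8)
        assert not np.allclose(m.cov_robust, m_ind.cov_robust)


class TestHazardRatioCurve:
    def test_constant_under_proportional_hazards(self):
        obs, d, arm = simulate_two_arm_exponential(2000, hr=0.5, seed=9)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        hr = fpm.hazard_ratio_curve(m, np.linspace(0.2, 2.5, 10))
        np.testing.assert_allclose(hr["hr"], np.exp(m.beta), rtol=1e-10)
        assert (hr["lcl"] <= hr["hr"]).all() and (hr["hr"] <= hr["ucl"]).all()

    def test_zero_tvc_coefficients_reduce_to_ph_curve(self):
        obs, d, arm = simulate_two_arm_exponential(2000, hr=0.5, seed=9)
        m2 = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=2)
        m2.params[m2.n_baseline + 1:] = 0.0
        hr = fpm.hazard_ratio_curve(m2, np.linspace(0.2, 2.5, 5))
        np.testing.assert_allclose(hr["hr"], np.exp(m2.beta), rtol=1e-10)

    def test_internal_consistency_hr_times_baseline(self):
        obs, d, arm = simulate_two_arm_exponential(2000, hr=0.6, seed=10)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=2)
        t = np.linspace(0.3, 2.0, 7)
        hr = fpm.hazard_ratio_curve(m, t)["hr"].to_numpy()
        np.testing.assert_allclose(hr * m.hazard(t, 0), m.hazard(t, 1), rtol=1e-10)

    def test_extrapolation_warns(self):
        obs, d, arm = simulate_two_arm_exponential(800, hr=0.8, seed=2)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=0)
        with pytest.warns(UserWarning, match="extrapolat"):
            fpm.hazard_ratio_curve(m, np.array([50.0]))

    def test_recovers_crossing_hazard_truth(self):
        """On the default crossing-hazards generator, the fitted curve is above 1
        immediately post-op and dips below 1 between 1 and 3 years."""
        cfg = SimConfig(n_procedures=30000, seed=31)
        cfg.revision_hazard.covariate_log_hr = {}
        cfg.propensity_coefs.coefs = {}
        cohort = registry.generate_cohort(cfg)
        a = (cohort["arm"] == "RTSR").astype(float).to_numpy()
        m = fpm.fit_fpm(cohort["revision_time"].to_numpy(),
                        cohort["revision_event"].to_numpy(), a)
        hr = fpm.hazard_ratio_curve(m, np.linspace(0.05, 6.0, 80))
        early = hr[hr.time < 0.25]["hr"]
        mid = hr[(hr.time > 1.0) & (hr.time < 3.0)]["hr"]
        assert early.iloc[0] > 1.0
        assert mid.min() < 1.0
        # the mid-term dip tracks the generator's configured deficit
        assert abs(np.log(mid.min()) - np.log(0.33)) < 0.7


class TestSurvivalCurves:
    def test_boundary_and_monotonicity(self):
        m = _exponential_model(0.3, log_hr=np.log(0.5))
        t = np.linspace(1e-3, 10, 200)
        curves = fpm.survival_curves(m, t)
        for a in (0, 1):
            s = curves[curves.arm == a]["survival"].to_numpy()
            assert s[0] > 0.999
            assert (np.diff(s) <= 1e-12).all()

    def test_matches_km_at_event_deciles(self):
        obs, d, arm = simulate_two_arm_exponential(20000, hr=0.7, rate0=0.5, seed=13)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=3, df_tvc=0)
        deciles = np.quantile(obs[d > 0], np.linspace(0.1, 0.9, 9))
        curves = fpm.survival_curves(m, deciles, km_data=(obs, d, arm))
        gap = (curves["survival"] - curves["km_survival"]).abs()
        assert gap.max() < 0.01


class TestRmst:
    def test_closed_form_exponential(self):
        m = _exponential_model(0.2)
        res = fpm.rmst_difference(m, t_star=5.0, seed=1, n_draws=100)
        closed = (1 - np.exp(-0.2 * 5.0)) / 0.2
        assert res.rmst["TSR"] == pytest.approx(closed, abs=5e-5)
        assert round(res.rmst["TSR"], 4) == round(closed, 4)

    def test_identical_arms_zero_difference(self):
        m = _exponential_model(0.2, log_hr=0.0)
        res = fpm.rmst_difference(m, t_star=5.0, seed=1, n_draws=200)
        assert res.difference == pytest.approx(0.0, abs=1e-9)
        assert res.ci[0] <= 0.0 <= res.ci[1]

    def test_quadrature_agrees_with_trapezoid_oracle(self):
        obs, d, arm = simulate_two_arm_exponential(2000, hr=0.6, seed=17)
        m = fpm.fit_fpm(obs, d, arm, df_baseline=2, df_tvc=2)
        res = fpm.rmst_difference(m, t_star=2.5, seed=1, n_draws=50)
        grid = np.linspace(1e-9, 2.5, 10001)
        trap = np.trapezoid(m.survival(grid, 1) - m.survival(grid, 0), grid)
        assert res.difference == pytest.approx(trap, abs=1e-6)

    def test_difference_equals_integral_of_survival_gap(self):
        m = _exponential_model(0.4, log_hr=np.log(0.5))
        res = fpm.rmst_difference(m, t_star=4.0, seed=1, n_draws=50)
        val, _ = integrate.quad(
            lambda t: float(m.survival(np.array([t]), 1)[0]
                            - m.survival(np.array([t]), 0)[0]), 0, 4.0)
        assert res.difference == pytest.approx(val, abs=1e-7)

    def test_invalid_horizon_rejected(self):
        m = _exponential_model(0.2)
        with pytest.raises(ValueError):
            fpm.rmst_difference(m, t_star=-1.0)
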