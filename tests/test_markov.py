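import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arthrocomp import markov, registry
from arthrocomp.exceptions import EstimationError


def _exp_fit(rate: float, var: float = 0.0, arm: str = "TSR",
             endpoint: str = "revision") -> markov.ParametricFit:
    """Exponential fit object built directly (lifelines parameterisation:
    lambda_ is the mean survival time 1/rate)."""
    return markov.ParametricFit(
        family="exponential", params=np.array([1.0 / rate]),
        param_names=("lambda_",), cov=np.array([[var]]), aic=0.0,
        endpoint=endpoint, arm=arm,
    )


def _weibull_fit(scale, shape, cov=None, arm="TSR"):
    return markov.ParametricFit(
        family="weibull", params=np.array([scale, shape]),
        param_names=("lambda_", "rho_"),
        cov=np.zeros((2, 2)) if cov is None else cov, aic=0.0,
        endpoint="revision", arm=arm,
    )


def _costs(primary=5000.0, revision=5000.0, p_se=0.0, r_se=0.0, rate=0.035):
    return markov.CostInputs(
        primary_mean={"TSR": primary, "RTSR": primary},
        primary_se={"TSR": p_se, "RTSR": p_se},
        revision_mean={"TSR": revision, "RTSR": revision},
        revision_se={"TSR": r_se, "RTSR": r_se},
        discount_rate=rate,
    )


class TestFitParametric:
    def test_exponential_rate_recovery_and_extrapolation(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(20.0, 10000)  # rate 0.05
        obs = np.minimum(t, 25.0)
        d = (t <= 25.0).astype(float)
        fit = markov.fit_parametric(obs, d, family="exponential")
        se = np.sqrt(fit.cov[0, 0])
        assert abs(fit.params[0] - 20.0) < 3 * se
        s10 = fit.survival(np.array([10.0]))[0]
        assert s10 == pytest.approx(np.exp(-10.0 / fit.params[0]), rel=1e-10)
        assert s10 == pytest.approx(np.exp(-0.5), rel=0.03)

    def test_weibull_nests_exponential_on_exponential_data(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10.0, 5000)
        d = np.ones_like(t)
        f_exp = markov.fit_parametric(t, d, family="exponential")
        f_wei = markov.fit_parametric(t, d, family="weibull")
        assert abs(f_wei.aic - f_exp.aic) < 2.5

    def test_auto_prefers_lower_aic(self):
        rng = np.random.default_rng(3)
        t = stats.weibull_min.rvs(0.6, scale=8.0, size=8000, random_state=rng)
        fit = markov.fit_parametric(t, np.ones_like(t), family="auto")
        f_exp = markov.fit_parametric(t, np.ones_like(t), family="exponential")
        assert fit.aic <= f_exp.aic

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            markov.fit_parametric(np.array([-1.0, 2.0]), np.array([1, 1]))


class TestBuildSchedule:
    def test_memoryless_constant_probability(self):
        sched = markov.build_schedule(_exp_fit(0.05), _exp_fit(1e-9), n_cycles=30)
        expected = 1 - np.exp(-0.05)
        np.testing.assert_allclose(sched.p_rev, expected, rtol=1e-9)
        assert expected == pytest.approx(0.04877, abs=5e-6)

    def test_zero_death_hazard(self):
        sched = markov.build_schedule(_exp_fit(0.1), _exp_fit(1e-12), n_cycles=10)
        np.testing.assert_allclose(sched.p_death, 0.0, atol=1e-10)

    def test_matches_conditional_probability_oracle(self):
        """Schedule equals (S(n-1)-S(n))/S(n-1) computed from scipy frozen
        distributions on a 40-cycle grid."""
        rev = _weibull_fit(scale=120.0, shape=0.8)
        dth = _weibull_fit(scale=18.0, shape=1.4)
        sched = markov.build_schedule(rev, dth, n_cycles=40)
        grid = np.arange(41.0)
        for fit, got in ((rev, sched.p_rev), (dth, sched.p_death)):
            s = stats.weibull_min.sf(grid, fit.params[1], scale=fit.params[0])
            oracle = (s[:-1] - s[1:]) / s[:-1]
            np.testing.assert_allclose(got, oracle, atol=1e-10)

    def test_rescaling_caps_total_probability(self):
        with pytest.warns(UserWarning, match="rescaled"):
            sched = markov.build_schedule(_exp_fit(3.0), _exp_fit(3.0), n_cycles=5)
        np.testing.assert_allclose(sched.p_rev + sched.p_death, 1.0, atol=1e-12)


class TestLifeTableSwitch:
    def _profile(self):
        return pd.DataFrame({"weight": [0.6, 0.4], "sex": ["F", "M"], "age": [77, 74]})

    def test_switch_beyond_horizon_is_noop(self):
        sched = markov.build_schedule(_exp_fit(0.05), _exp_fit(0.02), n_cycles=10)
        lt = registry.generate_life_table()
        assert markov.apply_life_table_switch(sched, lt, 10, self._profile()) is sched

    def test_absorbing_flood_with_certain_death(self):
        sched = markov.build_schedule(_exp_fit(0.01), _exp_fit(0.02), n_cycles=10)
        lt = pd.DataFrame([(a, s, 1.0) for a in range(60, 130) for s in "FM"],
                          columns=["age", "sex", "qx"])
        out = markov.apply_life_table_switch(sched, lt, 2, self._profile())
        res = markov.run_cohort_model(out, _costs(), arm="TSR")
        unrevised = res.trace.set_index("cycle")["unrevised"]
        assert unrevised.loc[3] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.cost_stream[4:], 0.0)

    def test_two_stratum_hand_mixture(self):
        sched = markov.build_schedule(_exp_fit(0.02), _exp_fit(0.02), n_cycles=6)
        lt = registry.generate_life_table()
        out = markov.apply_life_table_switch(sched, lt, 4, self._profile())
        qx = lt.set_index(["sex", "age"])["qx"]
        for n in (5, 6):
            expected = 0.6 * qx.loc[("F", 77 + n)] + 0.4 * qx.loc[("M", 74 + n)]
            assert out.p_death[n - 1] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(out.p_rev, sched.p_rev)
        np.testing.assert_allclose(out.p_death[:4], sched.p_death[:4])


class TestCohortModel:
    def test_no_revisions_cost_is_primary_only(self):
        sched = markov.TransitionSchedule("TSR", np.zeros(20), np.full(20, 0.05))
        res = markov.run_cohort_model(sched, _costs(primary=6543.21), arm="TSR")
        assert res.lifetime_cost == pytest.approx(6543.21, abs=1e-12)

    def test_geometric_series_closed_form(self):
        n = 2000  # effectively infinite horizon
        sched = markov.TransitionSchedule("TSR", np.full(n, 0.1), np.zeros(n))
        res = markov.run_cohort_model(sched, _costs(primary=0.0, revision=5000.0),
                                      arm="TSR")
        v = 1 / 1.035
        closed = 5000.0 * 0.1 * v / (1 - 0.9 * v)
        assert res.lifetime_cost == pytest.approx(closed, abs=1e-6)
        assert round(closed, 2) == 3703.70
        # brute-force cycle summation oracle
        brute = sum(5000.0 * 0.9 ** (k - 1) * 0.1 * v**k for k in range(1, n + 1))
        assert res.lifetime_cost == pytest.approx(brute, abs=1e-8)

    def test_occupancy_conservation_and_absorption(self):
        sched = markov.build_schedule(_exp_fit(0.05), _exp_fit(0.03), n_cycles=40)
        res = markov.run_cohort_model(sched, _costs(), arm="TSR")
        total = res.trace[["unrevised", "revised", "dead"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        assert (res.trace["revised"].diff().dropna() >= -1e-15).all()
        assert (res.trace["dead"].diff().dropna() >= -1e-15).all()

    def test_exponential_tunnels_equal_homogeneous_chain_oracle(self):
        """With memoryless fits the tunnel structure is redundant: a 3-state
        homogeneous chain in closed form gives the same lifetime cost."""
        rate_r, rate_d, r = 0.04, 0.03, 0.035
        n = 40
        sched = markov.build_schedule(_exp_fit(rate_r), _exp_fit(rate_d), n_cycles=n)
        res = markov.run_cohort_model(sched, _costs(primary=7000.0, revision=12000.0),
                                      arm="TSR")
        p_r = 1 - np.exp(-rate_r)
        p_d = 1 - np.exp(-rate_d)
        stay = 1 - p_r - p_d
        v = 1 / (1 + r)
        oracle = 7000.0 + sum(
            12000.0 * stay ** (k - 1) * p_r * v**k for k in range(1, n + 1)
        )
        assert res.lifetime_cost == pytest.approx(oracle, abs=1e-8)


class TestGammaAndMvn:
    def test_gamma_moment_matching(self):
        assert markov.gamma_from_moments(100.0, 10.0) == pytest.approx((100.0, 1.0))
        shape, scale = markov.gamma_from_moments(50.0, 50.0)
        assert shape == pytest.approx(1.0)  # exponential special case
        with pytest.raises(ValueError):
            markov.gamma_from_moments(-1.0, 1.0)

    def test_gamma_sampling_mean(self):
        shape, scale = markov.gamma_from_moments(100.0, 10.0)
        draws = np.random.default_rng(5).gamma(shape, scale, 100000)
        assert abs(draws.mean() - 100.0) < 3 * 10.0 / np.sqrt(100000)

    def test_mvn_zero_covariance_degenerate(self):
        mu = np.array([1.0, -2.0, 3.0])
        draws = markov.mvn_draws(mu, np.zeros((3, 3)), 10, seed=1)
        np.testing.assert_allclose(draws, np.tile(mu, (10, 1)))

    def test_mvn_reproducible_and_calibrated(self):
        cov = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, -0.2], [0.1, -0.2, 0.5]])
        a = markov.mvn_draws(np.zeros(3), cov, 100000, seed=7)
        b = markov.mvn_draws(np.zeros(3), cov, 100000, seed=7)
        np.testing.assert_array_equal(a, b)
        sample_cov = np.cov(a.T)
        assert np.abs((sample_cov - cov) / np.where(cov == 0, 1, cov)).max() < 0.05

    def test_mvn_non_psd_rejected_with_minor(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # leading minor 2 is negative
        with pytest.raises(EstimationError, match="order 2"):
            markov.mvn_draws(np.zeros(2), bad, 5, seed=1)


class TestPsa:
    def _fits(self, with_uncertainty=True):
        var = 0.25 if with_uncertainty else 0.0
        rev = {a: _exp_fit(0.04, var=var, arm=a) for a in ("TSR", "RTSR")}
        dth = {a: _exp_fit(0.03, var=var * 0.5, arm=a, endpoint="death")
               for a in ("TSR", "RTSR")}
        return rev, dth

    def test_zero_variance_collapses_to_deterministic(self):
        rev, dth = self._fits(with_uncertainty=False)
        res = markov.run_psa(rev, dth, _costs(), n_sims=200, seed=3)
        for arm in ("TSR", "RTSR"):
            np.testing.assert_allclose(res.draws[arm], res.deterministic[arm])
            assert res.interval[arm][0] == res.interval[arm][1]

    def test_psa_mean_close_to_deterministic(self):
        rev, dth = self._fits()
        res = markov.run_psa(rev, dth, _costs(p_se=100.0, r_se=400.0),
                             n_sims=10000, seed=4)
        for arm in ("TSR", "RTSR"):
            assert abs(res.mean[arm] / res.deterministic[arm] - 1) < 0.01

    def test_fixed_seed_bit_reproducible(self):
        rev, dth = self._fits()
        a = markov.run_psa(rev, dth, _costs(p_se=50.0), n_sims=500, seed=11)
        b = markov.run_psa(rev, dth, _costs(p_se=50.0), n_sims=500, seed=11)
        for arm in a.draws:
            np.testing.assert_array_equal(a.draws[arm], b.draws[arm])

    def test_seed_stream_stability_of_percentiles(self):
        rev, dth = self._fits()
        a = markov.run_psa(rev, dth, _costs(p_se=100.0, r_se=300.0),
                           n_sims=10000, seed=21)
        b = markov.run_psa(rev, dth, _costs(p_se=100.0, r_se=300.0),
                           n_sims=10000, seed=42)
        for arm in a.draws:
            for x, y in zip(a.interval[arm], b.interval[arm]):
                assert abs(x / y - 1) < 0.02


class TestDiscountSweep:
    def test_monotone_decreasing_in_rate_and_zero_rate_oracle(self):
        rev = {a: _exp_fit(0.05, arm=a) for a in ("TSR", "RTSR")}
        dth = {a: _exp_fit(0.02, arm=a, endpoint="death") for a in ("TSR", "RTSR")}
        sweep = markov.discount_sweep(rev, dth, _costs(revision=8000.0),
                                      [0.0, 0.035, 0.06], n_cycles=30)
        for arm in ("TSR", "RTSR"):
            sub = sweep[sweep.arm == arm].sort_values("discount_rate")
            costs = sub["lifetime_cost"].to_numpy()
            assert costs[0] > costs[1] > costs[2]
        # undiscounted equals a brute-force sum over the trace
        sched = markov.build_schedule(rev["TSR"], dth["TSR"], 30)
        res0 = markov.run_cohort_model(sched, _costs(revision=8000.0, rate=0.0))
        new_rev = res0.trace["revised"].diff().dropna().to_numpy()
        brute = 5000.0 + (8000.0 * new_rev).sum()
        assert res0.lifetime_cost == pytest.approx(brute, abs=1e-9)
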