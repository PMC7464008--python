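"""Tests for the hierarchical Bayesian machinery: WAIC, R-hat, MAP, fits."""

import math

import numpy as np
import pytest

from ewalearn import (
    CohortSpec,
    EWAParams,
    SamplerConfig,
    TaskConfig,
    compute_waic,
    fit_hierarchical,
    map_estimates,
    rhat,
    session_log_likelihood,
    simulate_cohort,
)
from ewalearn.cohort import constrain_params
from ewalearn.ewa import SessionData, TrialRecord
from ewalearn.hbayes import PosteriorResult, _constrain


class TestWAIC:
    def test_constant_loglik(self):
        ll = np.full((10, 7), -1.3)
        assert compute_waic(ll) == pytest.approx(-2 * 7 * -1.3)

    def test_two_draw_hand_arithmetic(self):
        ll = np.array([[-1.0], [-2.0]])
        lppd = math.log((math.exp(-1) + math.exp(-2)) / 2)
        p = np.var([-1.0, -2.0])
        assert compute_waic(ll) == pytest.approx(-2 * (lppd - p), abs=1e-12)

    def test_single_draw_branch(self):
        ll = np.array([[-1.0, -2.0]])
        assert compute_waic(ll) == pytest.approx(-2 * (-3.0))

    def test_agrees_with_arviz(self, rng):
        import arviz as az

        ll = -0.5 - 0.3 * rng.random((4, 100, 50))  # chains x draws x obs
        idata = az.from_dict(log_likelihood={"obs": ll})
        reference = float(az.waic(idata, scale="deviance").elpd_waic)
        ours = compute_waic(ll.reshape(400, 50))
        assert ours == pytest.approx(reference, abs=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.array([[0.0, -np.inf]]))


class TestRhat:
    def test_identical_constants_convention(self):
        assert rhat(np.ones((4, 100))) == 1.0

    def test_well_mixed_chains(self, rng):
        draws = rng.standard_normal((4, 1000))
        assert rhat(draws) < 1.05

    def test_disjoint_chains_flagged(self, rng):
        draws = rng.standard_normal((4, 500)) + np.arange(4)[:, None] * 10
        assert rhat(draws) > 1.5

    def test_close_to_arviz_on_gaussian_draws(self, rng):
        import arviz as az

        draws = rng.standard_normal((4, 1000))
        ours = rhat(draws)
        reference = float(az.rhat(az.from_dict(posterior={"x": draws})).x)
        assert ours == pytest.approx(reference, abs=0.02)


def _toy_result(theta, log_density):
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[2]
    return PosteriorResult(
        theta=theta,
        mu=np.zeros((theta.shape[0], theta.shape[1], 3)),
        sigma=np.ones((theta.shape[0], theta.shape[1], 3)),
        log_density=np.asarray(log_density, dtype=float),
        participant_ids=[f"P{i}" for i in range(n)],
        config=SamplerConfig(chains=theta.shape[0], draws=theta.shape[1], warmup=0),
        rhat={},
        converged=True,
        accept_rate=1.0,
    )


class TestMAP:
    def test_single_draw_returns_its_values(self):
        theta = np.array([[[[0.3, -0.4, -1.0]]]])  # 1 chain, 1 draw, 1 participant
        result = _toy_result(theta, [[-5.0]])
        for method in ("mode", "joint_draw"):
            (est,) = map_estimates(result, method=method)
            a, r, b = _constrain(theta[0, 0])[0][0], _constrain(theta[0, 0])[1][0], _constrain(theta[0, 0])[2][0]
            assert est.alpha == pytest.approx(float(a))
            assert est.rho == pytest.approx(float(r))
            assert est.beta == pytest.approx(float(b))

    def test_joint_draw_picks_highest_density(self):
        theta = np.array([[[[0.0, 0.0, 0.0]], [[1.0, 1.0, 1.0]]]])
        result = _toy_result(theta, [[-10.0, -5.0]])
        (est,) = map_estimates(result, method="joint_draw")
        a, r, b = _constrain(np.array([1.0, 1.0, 1.0]))
        assert est.alpha == pytest.approx(float(a))
        assert est.beta == pytest.approx(float(b))

    def test_mode_tracks_bulk_not_outlier(self, rng):
        # marginal mode should sit in the bulk even if the single
        # highest-density draw is elsewhere
        bulk = 0.5 + 0.05 * rng.standard_normal((1, 500, 1, 3))
        bulk[0, 0] = 3.0  # one extreme draw...
        dens = np.full((1, 500), -10.0)
        dens[0, 0] = 0.0  # ...that wins the joint-density race
        result = _toy_result(bulk, dens)
        (mode_est,) = map_estimates(result, method="mode")
        (draw_est,) = map_estimates(result, method="joint_draw")
        assert abs(mode_est.alpha - 0.69) < 0.05  # Phi(0.5) ~ 0.69
        assert draw_est.alpha > 0.99

    def test_missing_density_raises(self):
        result = _toy_result(np.zeros((1, 1, 1, 3)), [[0.0]])
        result.log_density = np.empty((0, 0))
        with pytest.raises(ValueError):
            map_estimates(result)


def test_prior_predictive_transforms_respect_bounds(rng):
    theta = 10.0 * rng.standard_normal((5000, 3))
    constrained = constrain_params(theta)
    assert np.all(constrained[:, 0] >= 0) and np.all(constrained[:, 0] <= 1)
    assert np.all(constrained[:, 1] >= 0) and np.all(constrained[:, 1] <= 1)
    assert np.all(constrained[:, 2] >= 0)


class TestFit:
    @pytest.fixture(scope="class")
    def small_fit(self):
        spec = CohortSpec(n_participants=4, seed=13)
        sessions, _, truth = simulate_cohort(spec)
        config = SamplerConfig(chains=2, draws=60, warmup=80, seed=3)
        with pytest.warns(UserWarning):  # short run: convergence flagged
            result = fit_hierarchical(sessions, config)
        return sessions, result

    def test_shapes_and_diagnostics(self, small_fit):
        sessions, result = small_fit
        assert result.theta.shape == (2, 60, 4, 3)
        assert result.mu.shape == (2, 60, 3)
        assert set(result.rhat) == {
            "mu_alpha", "mu_rho", "mu_beta",
            "sigma_alpha", "sigma_rho", "sigma_beta",
            "theta_max",
        }
        assert all(np.isfinite(v) for v in result.rhat.values())
        assert np.isfinite(result.waic)
        assert list(result.map_table.columns) == [
            "participant_id", "alpha_map", "rho_map", "beta_map",
        ]

    def test_pointwise_rows_match_session_likelihood(self, small_fit):
        sessions, result = small_fit
        n = len(sessions)
        n_obs = result.pointwise_loglik.shape[1] // n
        per_session = result.pointwise_loglik.reshape(-1, n, n_obs).sum(axis=2)
        for s_idx in (0, len(per_session) - 1):
            for i in (0, n - 1):
                a, r, b = result.pointwise_params[s_idx, i]
                want = session_log_likelihood(
                    sessions[i], EWAParams(a, r, b), "reversal"
                )
                assert per_session[s_idx, i] == pytest.approx(want, abs=1e-8)

    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_participants=3, seed=17)
        sessions, _, _ = simulate_cohort(spec)
        config = SamplerConfig(chains=2, draws=30, warmup=40, seed=5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = fit_hierarchical(sessions, config)
            r2 = fit_hierarchical(sessions, config)
        assert np.array_equal(r1.theta, r2.theta)
        assert np.array_equal(r1.log_density, r2.log_density)

    def test_flat_data_concentrates_beta_high(self):
        task = TaskConfig()
        trials = [
            TrialRecord(t, 0, 1 if t % 5 else 0, task.phase_of(t))
            for t in range(1, 81)
        ]
        session = SessionData("flat", trials, task)
        config = SamplerConfig(chains=2, draws=150, warmup=200, seed=7)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fit_hierarchical([session], config)
        beta_draws = _constrain(result.theta)[2]
        assert np.median(beta_draws) > 2.0  # clearly greedy for one stimulus

    def test_empty_sessions_rejected(self):
        with pytest.raises(ValueError):
            fit_hierarchical([])
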