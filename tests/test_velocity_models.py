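import math

import numpy as np
import pytest

from velodirect import (
    KineticParams,
    dynamic_likelihood,
    dynamic_velocity,
    fit_dynamic,
    fit_dynamic_em,
    fit_gamma,
    fit_steady_state,
    solve_kinetics,
    steady_state_velocity,
)
from velodirect.errors import ParameterError, ShapeError


class TestFitGamma:
    def test_exact_proportionality(self):
        s = np.array([1.0, 2.0, 5.0])
        assert fit_gamma(2 * s, s) == pytest.approx(2.0)

    def test_hand_example(self):
        assert fit_gamma(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(0.5)

    def test_identity_slope(self):
        v = np.array([1.0, 2.0, 3.0])
        assert fit_gamma(v, v) == pytest.approx(1.0)

    def test_all_zero_s_raises(self):
        with pytest.raises(ParameterError):
            fit_gamma(np.array([1.0, 2.0]), np.zeros(2))

    def test_vectorized_invalid_gene_flagged(self):
        Mu = np.array([[1.0, 1.0], [2.0, 2.0]])
        Ms = np.array([[1.0, 0.0], [2.0, 0.0]])
        fit = fit_steady_state(Mu, Ms)
        assert fit.valid.tolist() == [True, False]
        assert np.isnan(fit.gamma_tilde[1])

    def test_noisy_gamma_recovery_median_error(self):
        """Simulated equilibrium data with 10% multiplicative noise: median
        relative error of the recovered ratio < 5% over 100 genes."""
        rng = np.random.default_rng(12)
        n_cells, n_genes = 300, 100
        gamma_true = rng.uniform(0.1, 0.9, n_genes)
        s = rng.uniform(1.0, 10.0, (n_cells, n_genes))
        noise = lambda: np.exp(0.1 * rng.standard_normal((n_cells, n_genes)) - 0.005)
        u = gamma_true[None, :] * s * noise()
        fit = fit_steady_state(u, s * noise())
        rel_err = np.abs(fit.gamma_tilde - gamma_true) / gamma_true
        assert np.median(rel_err) < 0.05


class TestSteadyStateVelocity:
    def test_equilibrium_is_zero(self):
        s = np.abs(np.random.default_rng(0).normal(5, 1, (20, 3)))
        fit = fit_steady_state(0.5 * s, s)
        v = steady_state_velocity(0.5 * s, s, fit)
        np.testing.assert_allclose(v.velocity, 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        u = np.array([[1.0], [0.0]])
        s = np.array([[1.0], [1.0]])
        fit = fit_steady_state(u, s)
        v = steady_state_velocity(u, s, fit)
        np.testing.assert_allclose(v.velocity[:, 0], [0.5, -0.5])

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        u, s = rng.uniform(1, 5, (10, 4)), rng.uniform(1, 5, (10, 4))
        fit = fit_steady_state(u, s)
        v1 = steady_state_velocity(u, s, fit).velocity
        v2 = steady_state_velocity(2 * u, 2 * s, fit).velocity
        np.testing.assert_allclose(v2, 2 * v1)

    def test_centered_at_zero_on_simulated_steady_state(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(2, 8, (200, 20))
        u = 0.4 * s * np.exp(0.05 * rng.standard_normal((200, 20)))
        fit = fit_steady_state(u, s)
        v = steady_state_velocity(u, s, fit)
        assert abs(v.velocity.mean()) < 0.05

    def test_shape_mismatch(self):
        fit = fit_steady_state(np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ShapeError):
            steady_state_velocity(np.ones((3, 3)), np.ones((3, 3)), fit)


class TestDynamicLikelihood:
    def _params(self):
        return KineticParams(alpha=2.0, beta=1.0, gamma=0.5)

    def test_zero_residuals_sigma1(self):
        p = self._params()
        t = np.array([0.5, 1.5])
        u, s = solve_kinetics(p, t)
        L = dynamic_likelihood(p, 1.0, u, s, t)
        assert L == pytest.approx(1.0 / math.sqrt(2 * math.pi))

    def test_zero_residuals_sigma2(self):
        p = self._params()
        t = np.array([1.0])
        u, s = solve_kinetics(p, t)
        assert dynamic_likelihood(p, 2.0, u, s, t) == pytest.approx(1.0 / (2 * math.sqrt(2 * math.pi)))

    def test_unit_residual_norms(self):
        # 2 cells, each with residual norm 1, sigma=1, n=2 -> exp(-1/2)/sqrt(2*pi)
        p = self._params()
        t = np.array([0.5, 1.5])
        u, s = solve_kinetics(p, t)
        L = dynamic_likelihood(p, 1.0, u + 1.0, s, t)
        assert L == pytest.approx(math.exp(-0.5) / math.sqrt(2 * math.pi))

    def test_sigma_must_be_positive(self):
        p = self._params()
        with pytest.raises(ParameterError):
            dynamic_likelihood(p, 0.0, np.ones(2), np.ones(2), np.array([0.1, 0.2]))


class TestDynamicEM:
    def test_noiseless_parameter_recovery(self):
        """Rates recovered up to time scaling: (beta/alpha, gamma/alpha,
        alpha*t_switch) each within 10% on noiseless trajectory data."""
        rng = np.random.default_rng(3)
        p = KineticParams(alpha=2.0, beta=1.2, gamma=0.4, t_switch=3.0)
        t = np.sort(rng.uniform(0, 7.0, 120))
        u, s = solve_kinetics(p, t)
        res = fit_dynamic_em(u, s, max_iter=30)
        assert res["beta"] == pytest.approx(p.beta / p.alpha, rel=0.10)
        assert res["gamma"] == pytest.approx(p.gamma / p.alpha, rel=0.10)
        assert res["t_switch"] == pytest.approx(p.alpha * p.t_switch, rel=0.10)

    def test_on_trajectory_data_is_fixed_point(self):
        # data generated exactly on the fitted trajectory: one more EM
        # iteration leaves the likelihood unchanged within tolerance
        rng = np.random.default_rng(4)
        p = KineticParams(alpha=1.0, beta=0.8, gamma=0.3, t_switch=4.0)
        t = np.sort(rng.uniform(0, 9.0, 60))
        u, s = solve_kinetics(p, t)
        res = fit_dynamic_em(u, s, max_iter=40, tol=1e-9)
        tr = res["loglik_trace"]
        assert res["converged"]
        assert abs(tr[-1] - tr[-2]) < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_monotone_random_data(self, seed):
        rng = np.random.default_rng(seed)
        p = KineticParams(alpha=rng.uniform(1, 3), beta=rng.uniform(0.5, 2),
                          gamma=rng.uniform(0.2, 0.8), t_switch=rng.uniform(2, 5))
        t = np.sort(rng.uniform(0, 8.0, 60))
        u, s = solve_kinetics(p, t)
        u = u * np.exp(0.15 * rng.standard_normal(60))
        s = s * np.exp(0.15 * rng.standard_normal(60))
        tr = fit_dynamic_em(u, s, max_iter=12)["loglik_trace"]
        assert np.all(np.diff(tr) >= -1e-9)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ParameterError):
            fit_dynamic_em(np.ones(5), np.ones(5))


class TestDynamicVelocity:
    def _fit(self, u, s):
        return fit_dynamic(u, s, max_iter=15)

    def test_equilibrium_ratio_gives_zero(self):
        # direct arithmetic check on the formula via a hand-built fit
        import pandas as pd

        from velodirect.velocity_models import DynamicFit

        theta = pd.DataFrame({"alpha": [1.0], "beta": [1.0], "gamma": [0.5],
                              "t_switch": [2.0]})
        dfit = DynamicFit(theta=theta, sigma=np.array([0.1]),
                          latent_time=np.zeros((2, 1)), loglik_trace=[None],
                          converged=np.array([True]), valid=np.array([True]))
        s = np.array([[2.0], [4.0]])
        u = 0.5 * s                      # u = (gamma/beta) * s -> v = 0
        v = dynamic_velocity(u, s, dfit)
        np.testing.assert_allclose(v.velocity, 0.0, atol=1e-12)
        # beta=1, gamma=0.5, u=2, s=2 -> v = 1
        v2 = dynamic_velocity(np.array([[2.0]]), np.array([[2.0]]), dfit)
        assert v2.velocity[0, 0] == pytest.approx(1.0)

    def test_sign_tracks_kinetic_phase(self):
        """Velocity positive during induction and negative during repression
        on noiseless simulated data, for both estimators."""
        p = KineticParams(alpha=2.0, beta=1.0, gamma=0.3, t_switch=5.0)
        t_ind = np.linspace(0.2, 4.0, 40)
        t_rep = np.linspace(5.5, 12.0, 40)
        t = np.concatenate([t_ind, t_rep])
        u, s = solve_kinetics(p, t)
        dfit = fit_dynamic(u[:, None], s[:, None], max_iter=25)
        v = dynamic_velocity(u[:, None], s[:, None], dfit).velocity[:, 0]
        assert np.all(v[:40] > 0)
        assert np.mean(v[40:] < 0) > 0.9

    def test_steady_and_dynamic_signs_correlate(self):
        # one full induction/repression cycle: the two estimators agree on
        # the sign of velocity for most cells, in particular induction cells
        p = KineticParams(alpha=2.0, beta=1.0, gamma=0.3, t_switch=5.0)
        t = np.linspace(0.2, 12.0, 80)
        u, s = solve_kinetics(p, t)
        ss = fit_steady_state(u[:, None], s[:, None])
        v_ss = steady_state_velocity(u[:, None], s[:, None], ss).velocity[:, 0]
        dfit = fit_dynamic(u[:, None], s[:, None], max_iter=20)
        v_dy = dynamic_velocity(u[:, None], s[:, None], dfit).velocity[:, 0]
        assert np.mean(np.sign(v_ss) == np.sign(v_dy)) > 0.8
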