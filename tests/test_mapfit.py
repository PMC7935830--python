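"""MAP estimator: objective, optimum, shrinkage, batch solver."""

import numpy as np
import pytest

import drvoss as d
from drvoss.mapfit import fit_many


def make_obs(pop, ref_cov, reg, times, eta=(0, 0, 0), noise_rng=None):
    ind = d.individual_parameters(pop, ref_cov, eta)
    y = np.array([d.css_concentration(ind, reg, t) for t in times])
    if noise_rng is not None:
        y = d.apply_residual_error(y, pop, noise_rng)
    return d.ObservationSet(tuple(times), tuple(y), reg, ref_cov)


class TestMapObjective:
    def test_empty_observations_prior_only(self, pop, ref_cov, reg800):
        obs = d.ObservationSet((), (), reg800, ref_cov)
        assert d.map_objective((0, 0, 0), obs, pop) == 0.0
        assert d.map_objective((0.1, 0, 0), obs, pop) > 0
        assert d.map_objective((0.1, -0.2, 0.3), obs, pop) == pytest.approx(
            0.1**2 / 0.238**2 + 0.2**2 / 0.353**2 + 0.3**2 / 0.575**2
        )

    def test_exact_observation_leaves_log_variance_term(self, pop, ref_cov, reg800):
        t = 4.0
        f = d.css_concentration(d.individual_parameters(pop, ref_cov), reg800, t)
        obs = d.ObservationSet((t,), (f,), reg800, ref_cov)
        g = f**2 * pop.sigma_exp**2 + pop.sigma_add**2
        assert d.map_objective((0, 0, 0), obs, pop) == pytest.approx(np.log(g))

    def test_fixed_eta_for_zero_omega(self, pop, ref_cov, reg800):
        pop0 = pop.replace(omega_v=0.0)
        obs = d.ObservationSet((4.0,), (3.0,), reg800, ref_cov)
        with pytest.raises(ValueError, match="fixed at 0"):
            d.map_objective((0.0, 0.5, 0.0), obs, pop0)
        assert np.isfinite(d.map_objective((0.1, 0.0, 0.1), obs, pop0))


class TestMapEstimate:
    def test_no_data_returns_prior_mode(self, pop, ref_cov, reg800):
        res = d.map_estimate(d.ObservationSet((), (), reg800, ref_cov), pop)
        assert res.eta_hat == (0.0, 0.0, 0.0)
        assert res.cl_hat == pytest.approx(12.6)
        assert res.converged

    def test_matches_grid_search_oracle(self, pop, ref_cov, reg800, rng):
        """Optimum is at least as good as a dense 3-D grid over +/-2 omega."""
        grid = [np.arange(-2 * w, 2 * w + 1e-9, 0.02) for w in pop.omegas]
        for _ in range(5):
            eta = rng.normal(0, pop.omegas)
            obs = make_obs(pop, ref_cov, reg800, (1.0, 4.0, 19.0), eta, rng)
            res = d.map_estimate(obs, pop)
            best = np.inf
            e1g, e2g, e3g = np.meshgrid(*grid, indexing="ij")
            vals = _grid_objective(pop, ref_cov, reg800, obs, e1g, e2g, e3g)
            best = vals.min()
            assert res.objective <= best + 1e-4

    def test_exact_recovery_in_small_noise_limit(self, pop, ref_cov, reg800):
        """With noise-free data and vanishing likelihood sigmas the posterior
        mode converges to the data-generating random effects."""
        eta_true = (0.2, -0.1, 0.3)
        sharp = pop.replace(sigma_exp=1e-4, sigma_add=1e-4)
        obs = make_obs(sharp, ref_cov, reg800, (0.0, 0.5, 1, 2, 3, 4, 5, 6), eta_true)
        res = d.map_estimate(obs, sharp)
        assert np.allclose(res.eta_hat, eta_true, atol=1e-3)

    def test_single_trough_shrinks_toward_prior(self, pop, ref_cov, reg800):
        """|eta_hat_CL| < |eta_true_CL| on average for sparse data (shrinkage)."""
        rng = np.random.default_rng(77)
        n = 1000
        eta_cl = np.full(n, 0.5)
        ind = [d.individual_parameters(pop, ref_cov, (e, 0, 0)) for e in eta_cl]
        f = np.array([[d.css_concentration(i, reg800, 0.0)] for i in ind])
        y = d.apply_residual_error(f, pop, rng)
        eta, _, conv = fit_many(
            pop, [0.0], y, np.full(n, 12.6), np.full(n, 137.0), np.full(n, 0.545),
            np.full(n, 800.0), np.full(n, 24.0),
        )
        assert np.mean(np.abs(eta[:, 0])) < 0.5
        assert conv.mean() > 0.99

    def test_error_information_monotonicity(self, pop, ref_cov, reg800):
        """Mean |eta_CL error| falls as the design grows richer."""
        rng = np.random.default_rng(123)
        n = 2000
        designs = [[0.0], [0.0, 4.0], [1.0, 4.0, 19.0], [0.0, 0.5, 1, 2, 3, 4, 5, 6]]
        eta_true = rng.normal(0, pop.omegas, size=(n, 3))
        maes = []
        for times in designs:
            times = np.asarray(times, float)
            cl = 12.6 * np.exp(eta_true[:, 0])
            v = 137.0 * np.exp(eta_true[:, 1])
            ka = 0.545 * np.exp(eta_true[:, 2])
            f = d.steady_state_conc(800, 24, cl[:, None], v[:, None], ka[:, None], times[None, :])
            eta, _, _ = fit_many(
                pop, times, f, np.full(n, 12.6), np.full(n, 137.0), np.full(n, 0.545),
                np.full(n, 800.0), np.full(n, 24.0),
            )
            maes.append(np.mean(np.abs(eta[:, 0] - eta_true[:, 0])))
        assert maes[0] > maes[1] > maes[2] > maes[3]

    def test_observation_order_invariance(self, pop, ref_cov, reg800):
        a = d.ObservationSet((1.0, 4.0, 19.0), (3.1, 4.0, 1.2), reg800, ref_cov)
        b = d.ObservationSet((19.0, 1.0, 4.0), (1.2, 3.1, 4.0), reg800, ref_cov)
        ra, rb = d.map_estimate(a, pop), d.map_estimate(b, pop)
        assert ra.eta_hat == rb.eta_hat and ra.objective == rb.objective


class TestBatchSolver:
    def test_batch_matches_scalar_path(self, pop, ref_cov, reg800, rng):
        n = 40
        eta = rng.normal(0, pop.omegas, size=(n, 3))
        times = np.array([1.0, 4.0, 19.0])
        cl = 12.6 * np.exp(eta[:, 0]); v = 137.0 * np.exp(eta[:, 1]); ka = 0.545 * np.exp(eta[:, 2])
        f = d.steady_state_conc(800, 24, cl[:, None], v[:, None], ka[:, None], times[None, :])
        y = np.maximum(
            f * np.exp(rng.normal(0, pop.sigma_exp, f.shape))
            + rng.normal(0, pop.sigma_add, f.shape),
            d.OBS_FLOOR,
        )
        be, bo, bc = fit_many(
            pop, times, y, np.full(n, 12.6), np.full(n, 137.0), np.full(n, 0.545),
            np.full(n, 800.0), np.full(n, 24.0),
        )
        assert bc.all()
        for i in range(n):
            obs = d.ObservationSet(tuple(times), tuple(y[i]), reg800, ref_cov)
            res = d.map_estimate(obs, pop)
            assert bo[i] == pytest.approx(res.objective, abs=1e-6)


class TestAucFromMap:
    def test_arithmetic(self, reg800):
        res = d.MapResult((0, 0, 0), 12.6, 137.0, 0.545, 0.0, True)
        assert d.auc_from_map(res, reg800) == pytest.approx(800 / 12.6)

    def test_reciprocal_scaling(self, reg800):
        a = d.MapResult((0, 0, 0), 12.6, 137.0, 0.545, 0.0, True)
        b = d.MapResult((0, 0, 0), 6.3, 137.0, 0.545, 0.0, True)
        assert d.auc_from_map(b, reg800) == pytest.approx(2 * d.auc_from_map(a, reg800))


def _grid_objective(pop, cov, reg, obs, e1, e2, e3):
    """Vectorised MAP objective over an eta grid (independent oracle)."""
    times = np.asarray(obs.times)
    y = np.asarray(obs.conc)
    cl = 12.6 * np.exp(e1)[..., None]
    v = 137.0 * np.exp(e2)[..., None]
    ka = 0.545 * np.exp(e3)[..., None]
    f = d.steady_state_conc(reg.dose, reg.tau, cl, v, ka, times)
    g = f**2 * pop.sigma_exp**2 + pop.sigma_add**2
    val = ((y - f) ** 2 / g + np.log(g)).sum(axis=-1)
    val += (e1**2 / pop.omega_cl**2 + e2**2 / pop.omega_v**2 + e3**2 / pop.omega_ka**2)
    return val
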