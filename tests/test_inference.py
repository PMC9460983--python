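"""Likelihood, posterior, sampler and diagnostics."""

import numpy as np
import pytest
from scipy import stats

from peatflux import inference
from peatflux.params import ParameterSpace


class TestResidualsAndLikelihood:
    def test_perfect_model_zero_residual(self):
        e = np.array([[1e-4, 2e-4]])
        assert np.all(inference.residuals(e, e) == 0)

    def test_shift_gives_constant_residual(self):
        e = np.array([[1e-4, 2e-4, 3e-4]])
        np.testing.assert_allclose(inference.residuals(e + 5e-5, e), 5e-5)

    def test_single_proportional_error_point_at_mode(self):
        e_model = np.array([[2e-4]])
        eps = np.zeros((1, 1))
        sd = 0.3 * 2e-4
        got = inference.log_likelihood(eps, e_model, alpha=-10.0, beta_w1=0.0,
                                       beta_w2=0.3, w1=np.array([False]))
        assert got == pytest.approx(-np.log(sd * np.sqrt(2 * np.pi)), rel=1e-12)

    def test_independence_doubles_the_log_density(self):
        e_model = np.array([[2e-4, 2e-4]])
        eps = np.full((1, 2), 3e-5)
        one = inference.log_likelihood(eps[:, :1], e_model[:, :1], -10, 0.0,
                                       0.3, np.array([False]))
        two = inference.log_likelihood(eps, e_model, -10, 0.0, 0.3,
                                       np.array([False]))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_brute_force_normal_summation(self, rng):
        """3 trees x 4 days, mixed error groups, vs an independent
        scipy.stats summation."""
        e_model = rng.uniform(5e-5, 6e-4, (3, 4))
        eps = rng.normal(0, 1e-4, (3, 4))
        eps[1, 2] = np.nan  # missing day is excluded
        alpha, bw1, bw2 = -9.0, 20.0, 0.3
        w1 = np.array([False, True, False])
        expected = 0.0
        for i in range(3):
            for j in range(4):
                if not np.isfinite(eps[i, j]):
                    continue
                sd = (np.exp(alpha + bw1 * e_model[i, j]) if w1[i]
                      else bw2 * e_model[i, j])
                sd = max(sd, inference.SD_FLOOR)
                expected += stats.norm.logpdf(eps[i, j], 0.0, sd)
        got = inference.log_likelihood(eps, e_model, alpha, bw1, bw2, w1)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_error_sd_floor_engages_at_zero_model(self):
        sd = inference.error_sd(np.zeros((1, 1)), -10, 0.0, 0.3,
                                np.array([False]))
        assert sd[0, 0] == inference.SD_FLOOR


class TestLogPosterior:
    def test_flat_prior_identity_and_box(self, tiny_dataset):
        space = ParameterSpace("FM", n_trees=tiny_dataset.n_trees)
        lp = inference.make_log_posterior(tiny_dataset, space)
        rng = np.random.default_rng(3)
        a, b = space.sample_prior(rng, 2)
        assert np.isfinite(lp(a)) and np.isfinite(lp(b))
        # posterior ordering equals likelihood ordering under flat priors
        assert (lp(a) > lp(b)) == (lp(a) - lp(b) > 0)
        outside = a.copy()
        outside[space.index("gamma")] = 1.0
        assert lp(outside) == -np.inf

    def test_boundary_point_is_finite(self, tiny_dataset):
        space = ParameterSpace("FM", n_trees=tiny_dataset.n_trees)
        assert np.isfinite(inference.make_log_posterior(tiny_dataset, space)
                           (space.lower.copy()))


class _ToyGaussianSpace:
    """Minimal stand-in space: 2-d Gaussian target inside a wide box."""

    names = ["x", "y"]
    ndim = 2
    lower = np.array([-10.0, -10.0])
    upper = np.array([10.0, 10.0])

    def in_box(self, v):
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def sample_prior(self, rng, n):
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))


def _toy_logpost(v):
    mean = np.array([1.0, -2.0])
    return -0.5 * np.sum((v - mean) ** 2 / np.array([0.5, 2.0]))


class TestSampler:
    def test_recovers_toy_gaussian_moments(self):
        space = _ToyGaussianSpace()
        chain = inference.run_mcmc(_toy_logpost, space, n_walkers=24,
                                   n_steps=1500, seed=42)
        flat = chain.flat
        np.testing.assert_allclose(flat.mean(axis=0), [1.0, -2.0], atol=0.15)
        np.testing.assert_allclose(flat.var(axis=0), [0.5, 2.0], rtol=0.25)

    def test_identical_chains_for_identical_seeds(self):
        space = _ToyGaussianSpace()
        a = inference.run_mcmc(_toy_logpost, space, n_walkers=12, n_steps=200,
                               seed=7)
        b = inference.run_mcmc(_toy_logpost, space, n_walkers=12, n_steps=200,
                               seed=7)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_retained_half_bookkeeping(self):
        space = _ToyGaussianSpace()
        chain = inference.run_mcmc(_toy_logpost, space, n_walkers=12,
                                   n_steps=100, seed=1)
        assert chain.retained.shape == (12, 50, 2)
        np.testing.assert_array_equal(chain.retained[:, 0], chain.draws[50])


class TestGelmanRubin:
    def test_identical_chains_guarded_to_one(self):
        c = np.tile(np.linspace(0, 1, 50), (3, 1))[:, :, None]
        const = np.ones((3, 50, 1))
        assert inference.gelman_rubin(const)[0] == 1.0
        # identical but non-constant chains: B = 0, so R-hat = sqrt((n-1)/n)
        assert inference.gelman_rubin(c)[0] == pytest.approx(
            np.sqrt(49 / 50), rel=1e-12)

    def test_same_distribution_approaches_one(self, rng):
        chains = rng.standard_normal((4, 4000, 2))
        assert np.all(inference.gelman_rubin(chains) < 1.05)

    def test_disjoint_means_flagged(self, rng):
        chains = rng.standard_normal((2, 500, 1))
        chains[1] += 10.0
        assert inference.gelman_rubin(chains)[0] > 1.5


class TestMapAndBands:
    def _chain(self, draws, logp, space=None):
        return inference.PosteriorChain(draws=draws, log_prob=logp,
                                        space=space or _ToyGaussianSpace(),
                                        seed=0, acceptance=1.0)

    def test_single_draw_is_its_own_map(self):
        draws = np.array([[[3.0, 4.0]]] * 2)
        logp = np.array([[-1.0], [-1.0]])
        np.testing.assert_array_equal(
            inference.map_estimate(self._chain(draws, logp)), [3.0, 4.0])

    def test_injected_best_draw_is_returned(self, rng):
        draws = rng.standard_normal((40, 6, 2))
        logp = rng.uniform(-5, -1, (40, 6))
        draws[33, 2] = [9.0, 9.0]
        logp[33, 2] = 0.0
        np.testing.assert_array_equal(
            inference.map_estimate(self._chain(draws, logp)), [9.0, 9.0])

    def test_map_near_toy_mode(self):
        chain = inference.run_mcmc(_toy_logpost, _ToyGaussianSpace(),
                                   n_walkers=24, n_steps=1500, seed=9)
        np.testing.assert_allclose(inference.map_estimate(chain),
                                   [1.0, -2.0], atol=0.3)

    def test_noise_free_band_collapses_to_the_simulation(self, tiny_dataset):
        from peatflux.forward import simulate
        ds = tiny_dataset
        space = ParameterSpace("FM", n_trees=ds.n_trees)
        v = space.sample_prior(np.random.default_rng(2), 1)[0]
        v[space.index("alpha")] = -15.0
        v[space.index("beta_w1")] = 0.0
        v[space.index("beta_w2")] = 0.0
        draws = np.broadcast_to(v, (2, 1, v.size)).copy()
        chain = self._chain(draws, np.zeros((2, 1)), space)
        band = inference.predictive_interval(chain, ds, n_samples=200, seed=5)
        e = simulate(ds, space.decode(v)).e_model
        np.testing.assert_allclose(band[0], e, atol=1e-6)
        np.testing.assert_allclose(band[1], e, atol=1e-6)

    def test_larger_noise_widens_the_band_everywhere(self, tiny_dataset):
        ds = tiny_dataset
        space = ParameterSpace("FM", n_trees=ds.n_trees)
        v = space.sample_prior(np.random.default_rng(2), 1)[0]
        widths = []
        for beta in (0.1, 0.4):
            w = v.copy()
            w[space.index("beta_w2")] = beta
            w[space.index("alpha")] = -15.0
            w[space.index("beta_w1")] = 0.0
            draws = np.broadcast_to(w, (2, 1, w.size)).copy()
            chain = self._chain(draws, np.zeros((2, 1)), space)
            band = inference.predictive_interval(chain, ds, n_samples=400, seed=6)
            widths.append(band[1] - band[0])
        assert np.all(widths[1] >= widths[0] - 1e-12)


class TestParameterRecovery:
    def test_truth_inside_credible_intervals(self, recovery_fit):
        """On synthetic data from a known interior truth, the marginal 95%
        intervals should cover most of the 22 parameters."""
        res, truth = recovery_fit["result"], recovery_fit["truth"]
        covered = (res.q_low <= truth) & (truth <= res.q_high)
        assert covered.mean() >= 0.8

    def test_sampler_reports_convergence_status(self, recovery_fit):
        res = recovery_fit["result"]
        assert res.rhat.shape == (res.space.ndim,)
        assert isinstance(res.converged, bool)
        # diagnostics must come from the retained halves only
        assert res.chain.retained.shape[1] == res.chain.n_steps // 2
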