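import numpy as np
import pytest

import poismrf as pm
from poismrf import _kernels as K
from poismrf.exceptions import ConfigurationError

TINY_CHAIN = pm.ChainConfig(n_iter=400, burn_in=100, thin=5, seed=42)


class TestDeterminismAndSupport:
    def test_same_seed_same_chain(self, small_problem):
        truth, obs, A, G = small_problem
        cfg = pm.PriorConfig()
        a = pm.run_chain(obs, A, G, cfg, TINY_CHAIN)
        b = pm.run_chain(obs, A, G, cfg, TINY_CHAIN)
        np.testing.assert_array_equal(a.draws_x, b.draws_x)
        np.testing.assert_array_equal(a.draws_tau, b.draws_tau)

    def test_all_draws_nonnegative(self, small_problem):
        truth, obs, A, G = small_problem
        chain = pm.run_chain(obs, A, G, pm.PriorConfig(), TINY_CHAIN)
        assert np.all(chain.draws_x >= 0)
        assert np.all(chain.draws_tau >= pm.PriorConfig().tau_floor)

    def test_logpost_matches_python_evaluation(self, small_problem):
        """Saved log-posterior values agree with the independent evaluation."""
        truth, obs, A, G = small_problem
        cfg = pm.PriorConfig()
        chain = pm.run_chain(obs, A, G, cfg, TINY_CHAIN)
        k = chain.n_draws - 1
        cfg_state = pm.PriorConfig(
            mode="inhomogeneous", tau_vec=chain.draws_tau[k], sample_tau=False,
            gamma_rate=cfg.gamma_rate,
        )
        x = pm.ImageGrid.from_vec(chain.draws_x[k], chain.n_rows, chain.n_cols, kind="truth")
        expected = pm.log_joint_posterior(obs, x, cfg_state, A, G)
        assert chain.log_post[k] == pytest.approx(expected, abs=1e-6)


class TestLocalDeltaCorrectness:
    def test_pixel_delta_matches_full_recomputation(self):
        """The sampler's local posterior delta equals the global difference."""
        rng = np.random.default_rng(11)
        truth = pm.ImageGrid(rng.uniform(0, 30, (5, 5)))
        A = pm.build_system_matrix(5, 5, 0.7)
        G = pm.build_neighborhood(5, 5)
        y = pm.simulate_observation(truth, A, pm.NoiseConfig(seed=1))
        x = np.maximum(y.vec(), 0.0) + 0.5
        tau = rng.uniform(0.5, 4.0, 25)
        lam = A.matrix @ x
        Aip = A.csc.indptr.astype(np.int64)
        Arow = A.csc.indices.astype(np.int64)
        Aval = A.csc.data.astype(np.float64)

        def full_logpost(xv):
            cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=tau, sample_tau=False)
            img = pm.ImageGrid.from_vec(xv, 5, 5, kind="truth")
            return pm.log_joint_posterior(y, img, cfg, A, G)

        base = full_logpost(x)
        for _ in range(100):
            j = int(rng.integers(25))
            xp = float(max(x[j] + rng.normal(0, 3), 0.0))
            d = K.pixel_delta(
                j, xp, x, tau, lam, y.vec(), Aip, Arow, Aval,
                G.indptr.astype(np.int64), G.indices.astype(np.int64),
                G.weights.astype(np.float64),
            )
            x2 = x.copy()
            x2[j] = xp
            assert d == pytest.approx(full_logpost(x2) - base, abs=1e-8)


class TestModelEquivalence:
    def test_fixed_tau_homogeneous_equals_pinned_inhomogeneous(self, small_problem):
        truth, obs, A, G = small_problem
        m = truth.n_pixels
        hom = pm.PriorConfig(mode="homogeneous", tau=2.5, sample_tau=False)
        pin = pm.PriorConfig(
            mode="inhomogeneous", tau_vec=np.full(m, 2.5), sample_tau=False
        )
        a = pm.run_chain(obs, A, G, hom, TINY_CHAIN)
        b = pm.run_chain(obs, A, G, pin, TINY_CHAIN)
        np.testing.assert_array_equal(a.draws_x, b.draws_x)


class TestSingleStepUpdates:
    def _state(self, small_problem):
        truth, obs, A, G = small_problem
        m = truth.n_pixels
        return (
            pm.ChainState(
                x=np.maximum(obs.vec(), 0.0),
                tau_vec=np.ones(m),
                gamma=1e-2,
                log_post=0.0,
            ),
            truth,
            obs,
            A,
            G,
        )

    def test_pixel_update_keeps_support(self, small_problem):
        state, truth, obs, A, G = self._state(small_problem)
        pm.seed_kernels(3)
        cfg = pm.PriorConfig()
        ccfg = pm.ChainConfig(n_iter=10, burn_in=0, thin=1)
        n_acc = 0
        for _ in range(200):
            j = 0
            state, acc = pm.mh_update_pixel(state, j, obs, A, G, cfg, ccfg)
            n_acc += acc
            assert state.x[j] >= 0.0
        assert 0 < n_acc < 200  # both outcomes occur

    def test_tau_update_degenerate_region_hits_floor(self):
        """With zero local energy the variance conditional collapses to the floor."""
        pm.seed_kernels(4)
        floor = 1e-3
        samples = K.sample_tau_chain(4000, 5, 1.0, 0.0, 1e-2, 0.5, floor)
        assert np.all(samples >= floor)
        assert np.median(samples) < 0.5  # piles toward small values

    def test_gamma_fixed_is_warned_noop(self, small_problem):
        state, *_ = self._state(small_problem)
        g0 = state.gamma
        with pytest.warns(UserWarning):
            out = pm.gibbs_update_gamma(state, pm.PriorConfig(gamma_fixed=True))
        assert out.gamma == g0 == 1e-2

    def test_gamma_draws_match_conditional_moments(self, small_problem):
        state, *_ = self._state(small_problem)
        cfg = pm.PriorConfig(gamma_fixed=False, theta=0.01)
        pm.seed_kernels(5)
        m = state.tau_vec.size
        mean_expected = (m + 1) / (state.tau_vec.sum() + cfg.theta)
        sd_expected = np.sqrt(m + 1) / (state.tau_vec.sum() + cfg.theta)
        draws = []
        for _ in range(10_000):
            state = pm.gibbs_update_gamma(state, cfg)
            draws.append(state.gamma)
        draws = np.asarray(draws)
        assert np.all(draws > 0)
        se = sd_expected / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_expected) < 3 * se


class TestSummaries:
    def test_constant_chain(self):
        draws = np.full((50, 6), 4.0)
        chain = pm.Chain(
            draws_x=draws, draws_tau=np.ones_like(draws), draws_gamma=np.ones(50),
            log_post=np.zeros(50), accept_rate_x=1.0, accept_rate_tau=1.0,
            n_rows=2, n_cols=3, chain_config=TINY_CHAIN, prior_config=pm.PriorConfig(),
            exposure=1.0,
        )
        s = pm.summarize_chain(chain, truth=np.full((2, 3), 4.0))
        assert np.all(s.sd == 0)
        np.testing.assert_array_equal(s.lci, s.mean)
        np.testing.assert_array_equal(s.ucl, s.mean)
        np.testing.assert_array_equal(s.bias, 0.0)

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        draws = rng.gamma(2.0, 3.0, size=(1000, 4))
        chain = pm.Chain(
            draws_x=draws, draws_tau=np.ones_like(draws), draws_gamma=np.ones(1000),
            log_post=np.zeros(1000), accept_rate_x=0.5, accept_rate_tau=0.5,
            n_rows=2, n_cols=2, chain_config=TINY_CHAIN, prior_config=pm.PriorConfig(),
            exposure=1.0,
        )
        s = pm.summarize_chain(chain)
        np.testing.assert_allclose(s.lci, np.percentile(np.sort(draws, axis=0), 2.5, axis=0))
        np.testing.assert_allclose(s.ucl, np.percentile(np.sort(draws, axis=0), 97.5, axis=0))
        assert np.all(s.lci <= s.mean) and np.all(s.mean <= s.ucl)

    def test_empty_chain_rejected(self):
        chain = pm.Chain(
            draws_x=np.empty((0, 4)), draws_tau=np.empty((0, 4)), draws_gamma=np.empty(0),
            log_post=np.empty(0), accept_rate_x=0.0, accept_rate_tau=0.0,
            n_rows=2, n_cols=2, chain_config=TINY_CHAIN, prior_config=pm.PriorConfig(),
            exposure=1.0,
        )
        with pytest.raises(ConfigurationError):
            pm.summarize_chain(chain)


class TestConvergence:
    def test_dispersed_starts_mix(self, sharp_truth, system_matrix, graph, low_count_obs):
        """Chains from x0 = 0 and x0 = 2y agree (PSRF < 1.1) on random pixels."""
        cfg = pm.PriorConfig()
        y = low_count_obs
        chains = []
        for seed, x0 in ((21, np.zeros(y.n_pixels)), (22, 2.0 * y.vec())):
            ccfg = pm.ChainConfig(n_iter=3000, burn_in=1500, thin=5, seed=seed)
            chains.append(
                pm.run_chain(y, system_matrix, graph, cfg, ccfg, exposure=0.25, x0=x0)
            )
        rng = np.random.default_rng(0)
        pixels = rng.choice(y.n_pixels, size=20, replace=False)
        rhat = pm.potential_scale_reduction([c.draws_x[:, pixels] for c in chains])
        assert np.all(rhat < 1.1)
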