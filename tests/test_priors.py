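import numpy as np
import pytest
import scipy.integrate as si
from hypothesis import given, settings
from hypothesis import strategies as st

import poismrf as pm
from poismrf.exceptions import ConfigurationError


class TestNeighborhood:
    def test_degrees_on_3x3(self):
        G = pm.build_neighborhood(3, 3)
        assert G.degree(4) == 4  # centre
        assert G.degree(0) == 2  # corner
        assert G.degree(1) == 3  # edge

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 12), st.integers(2, 12))
    def test_edge_count_and_symmetry(self, r, c):
        G = pm.build_neighborhood(r, c)
        assert G.n_directed_edges == 2 * (2 * r * c - r - c)
        # symmetry: t in d(j) <=> j in d(t) with equal weight
        pairs = {}
        for j in range(G.n_sites):
            idx, w = G.neighbors(j)
            for t, wv in zip(idx, w):
                pairs[(j, t)] = wv
        for (j, t), wv in pairs.items():
            assert pairs[(t, j)] == wv

    def test_3d_stacked_grid_has_six_neighbours(self):
        G = pm.build_neighborhood(3, 3, order="first_3d", n_layers=3)
        centre = (1 * 3 + 1) * 3 + 1  # middle layer, middle pixel
        assert G.degree(centre) == 6


class TestLocalEnergy:
    def test_constant_image_zero(self):
        G = pm.build_neighborhood(4, 4)
        x = np.full(16, 3.0)
        assert pm.local_energy(x, 5, G) == 0.0

    def test_hand_sum_2x2(self):
        G = pm.build_neighborhood(2, 2)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pm.local_energy(x, 0, G) == pytest.approx(3.0)  # |1-2| + |1-3|

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        G = pm.build_neighborhood(4, 4)
        x = rng.uniform(0, 10, 16)
        for j in range(16):
            expected = 0.0
            r, c = divmod(j, 4)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < 4 and 0 <= cc < 4:
                    expected += abs(x[j] - x[rr * 4 + cc])
            assert pm.local_energy(x, j, G) == pytest.approx(expected)


class TestLogPrior:
    def test_constant_image_homogeneous(self):
        G = pm.build_neighborhood(3, 5)
        cfg = pm.PriorConfig(mode="homogeneous", tau=2.0)
        x = np.full(15, 7.0)
        assert pm.log_prior(x, G, cfg) == pytest.approx(-15 * np.log(4.0))

    def test_doubling_tau_shifts_normalizer(self):
        G = pm.build_neighborhood(3, 3)
        x = np.full(9, 1.0)
        a = pm.log_prior(x, G, pm.PriorConfig(mode="inhomogeneous", tau_vec=np.full(9, 2.0), sample_tau=False))
        b = pm.log_prior(x, G, pm.PriorConfig(mode="inhomogeneous", tau_vec=np.full(9, 4.0), sample_tau=False))
        assert a - b == pytest.approx(9 * np.log(2.0))

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(4)
        G = pm.build_neighborhood(3, 3)
        x = rng.uniform(0, 5, 9)
        tau = rng.uniform(0.5, 3.0, 9)
        cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=tau, sample_tau=False)
        expected = sum(
            -np.log(2 * tau[j]) - pm.local_energy(x, j, G) / tau[j] for j in range(9)
        )
        assert pm.log_prior(x, G, cfg) == pytest.approx(expected)

    def test_homogeneous_equals_pinned_inhomogeneous(self):
        rng = np.random.default_rng(5)
        G = pm.build_neighborhood(4, 5)
        x = rng.uniform(0, 9, 20)
        hom = pm.PriorConfig(mode="homogeneous", tau=1.7)
        inh = pm.PriorConfig(mode="inhomogeneous", tau_vec=np.full(20, 1.7), sample_tau=False)
        assert pm.log_prior(x, G, hom) == pm.log_prior(x, G, inh)


class TestHyperprior:
    def test_single_unit_case(self):
        cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=np.array([1.0]), gamma_rate=1.0,
                             gamma_fixed=True, sample_tau=False)
        assert pm.log_hyperprior(cfg) == pytest.approx(-1.0)

    def test_two_pixel_case(self):
        cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=np.array([1.0, 3.0]),
                             gamma_rate=0.5, gamma_fixed=True, sample_tau=False)
        assert pm.log_hyperprior(cfg) == pytest.approx(2 * np.log(0.5) - 2.0)

    def test_density_integrates_to_one(self):
        g = 0.7
        val, _ = si.quad(lambda t: g * np.exp(-g * t), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_sampled_gamma_adds_hyper_hyper_term(self):
        tv = np.array([1.0, 3.0])
        fixed = pm.PriorConfig(mode="inhomogeneous", tau_vec=tv, gamma_rate=0.5,
                               gamma_fixed=True, sample_tau=False)
        sampled = pm.PriorConfig(mode="inhomogeneous", tau_vec=tv, gamma_rate=0.5,
                                 gamma_fixed=False, theta=0.2, sample_tau=False)
        diff = pm.log_hyperprior(sampled) - pm.log_hyperprior(fixed)
        assert diff == pytest.approx(np.log(0.2) - 0.2 * 0.5)


class TestJointPosterior:
    def test_is_sum_of_components(self, small_problem):
        truth, obs, A, G = small_problem
        tau = np.random.default_rng(1).uniform(0.5, 5, truth.n_pixels)
        cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=tau, sample_tau=False)
        lp = pm.log_joint_posterior(obs, truth, cfg, A, G)
        lam = pm.forward_project(A, truth)
        expected = (
            pm.poisson_loglik(obs.vec(), lam)
            + pm.log_prior(truth, G, cfg)
            + pm.log_hyperprior(cfg)
        )
        assert lp == pytest.approx(expected)

    def test_vanishing_tau_with_energy_diverges(self, small_problem):
        truth, obs, A, G = small_problem
        m = truth.n_pixels
        vals = []
        for t0 in (1.0, 1e-2, 1e-4):
            tau = np.ones(m)
            tau[5] = t0
            cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=tau, sample_tau=False,
                                 tau_floor=1e-6)
            vals.append(pm.log_joint_posterior(obs, truth, cfg, A, G))
        assert vals[0] > vals[1] > vals[2]

    def test_1x2_pencil_and_paper(self):
        # y = (2, 1), x = (3, 1), A = I, tau = (2, 4), gamma = 0.5 fixed
        A = pm.build_system_matrix(1, 2, 0.0)
        G = pm.build_neighborhood(1, 2)
        cfg = pm.PriorConfig(mode="inhomogeneous", tau_vec=np.array([2.0, 4.0]),
                             gamma_rate=0.5, gamma_fixed=True, sample_tau=False)
        y = pm.ImageGrid(np.array([[2.0, 1.0]]), kind="observation")
        x = pm.ImageGrid(np.array([[3.0, 1.0]]))
        lik = (2 * np.log(3) - 3 - np.log(2)) + (1 * np.log(1) - 1 - 0)
        prior = (-np.log(4) - 2 / 2) + (-np.log(8) - 2 / 4)
        hyper = (np.log(0.5) - 0.5 * 2) + (np.log(0.5) - 0.5 * 4)
        assert pm.log_joint_posterior(y, x, cfg, A, G) == pytest.approx(lik + prior + hyper)


class TestTauConditional:
    def test_mode_formula(self):
        cond = pm.tau_conditional_params(2.0, 0.5)
        assert cond.mode == pytest.approx((-1 + np.sqrt(5.0)), abs=1e-12)
        assert not cond.degenerate

    def test_mode_is_grid_argmax(self):
        cond = pm.tau_conditional_params(2.0, 0.5)
        grid = np.linspace(1e-3, 50, 200_000)
        argmax = grid[np.argmax(cond.log_density(grid))]
        assert argmax == pytest.approx(cond.mode, abs=1e-3)

    def test_zero_energy_flagged_degenerate(self):
        cond = pm.tau_conditional_params(0.0, 0.5)
        assert cond.degenerate
        assert cond.mode == 0.0

    def test_negative_energy_rejected(self):
        with pytest.raises(ConfigurationError):
            pm.tau_conditional_params(-1.0, 0.5)


class TestGammaConditional:
    def test_shape_rate_and_mean(self):
        shape, rate = pm.gamma_conditional_params(np.array([1.0, 3.0]), 0.01)
        assert (shape, rate) == (3.0, 4.01)
        assert shape / rate == pytest.approx(0.7481, abs=1e-4)

    def test_large_theta_drives_mean_to_zero(self):
        shape, rate = pm.gamma_conditional_params(np.array([1.0, 3.0]), 1e9)
        assert shape / rate < 1e-8

    def test_log_density_proportionality(self):
        # density prop to gamma^m exp(-gamma (sum tau + theta))
        tv = np.array([0.5, 2.0, 1.5])
        shape, rate = pm.gamma_conditional_params(tv, 0.3)
        from scipy.stats import gamma as gamma_dist

        gs = np.array([0.1, 0.5, 1.0, 2.0, 5.0])
        logpdf = gamma_dist.logpdf(gs, a=shape, scale=1 / rate)
        ref = tv.size * np.log(gs) - gs * (tv.sum() + 0.3)
        diffs = logpdf - ref
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-10)
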