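import itertools
import math

import numpy as np
import pytest
from sklearn.base import clone

from auxnet import (NetworkBlockModel, e_step, fit_blockmodel, icl_score,
                    jeffreys_substantial, lower_bound, m_step, model_scan,
                    n_parameters, partition_match, simulate_blockmodel_graph,
                    simulate_covariates, JEFFREYS_THRESHOLD)
from auxnet.blockmodel import BlockParameters

from conftest import random_symmetric


def _gaussian_params(alpha, mu, sigma2):
    return BlockParameters(family="gaussian", alpha=np.asarray(alpha, float),
                           mu=np.asarray(mu, float), sigma2=sigma2)


class TestEStep:
    def test_single_cluster_is_absorbing(self):
        rng = np.random.default_rng(0)
        X = random_symmetric(rng, 6)
        params = _gaussian_params([1.0], [[0.5]], 0.1)
        tau = e_step(X, None, params, np.ones((6, 1)))
        assert np.allclose(tau, 1.0)

    def test_symmetric_blocks_leave_uniform_tau_fixed(self):
        # pi_11 = pi_22 and pi_12 = pi_21 with uniform alpha: no information
        rng = np.random.default_rng(1)
        Z = (random_symmetric(rng, 8) > 0.5).astype(float)
        params = BlockParameters(family="bernoulli", alpha=np.array([0.5, 0.5]),
                                 mu=np.array([[0.4, 0.4], [0.4, 0.4]]))
        tau = e_step(Z, None, params, np.full((8, 2), 0.5))
        assert np.allclose(tau, 0.5)

    def test_separated_blocks_give_degenerate_posteriors(self):
        s = simulate_blockmodel_graph(_cfg(n=16, Q=2, mu=(0.9, 0.1), sigma=0.05,
                                           seed=4))
        params = _gaussian_params([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], 0.05 ** 2)
        tau0 = np.full((16, 2), 0.5)
        tau0[:, 0] += np.linspace(-0.01, 0.01, 16)  # break the symmetric point
        tau0 /= tau0.sum(1, keepdims=True)
        tau = e_step(s.network.X, None, params, tau0)
        assert np.all(np.abs(tau - np.round(tau)) < 1e-3)


def _cfg(**kw):
    from auxnet.simulate import SimulationConfig
    return SimulationConfig(**kw)


class TestMStep:
    def test_single_cluster_moments(self):
        rng = np.random.default_rng(2)
        X = random_symmetric(rng, 10)
        tau = np.ones((10, 1))
        p = m_step(X, None, tau, "gaussian")
        iu = np.triu_indices(10, 1)
        assert p.mu[0, 0] == pytest.approx(X[iu].mean(), abs=1e-9)
        assert p.sigma2 == pytest.approx(X[iu].var(), rel=1e-6)

    def test_single_cluster_regression_equals_ols(self):
        rng = np.random.default_rng(3)
        X = random_symmetric(rng, 12)
        Y = random_symmetric(rng, 12)[None]
        tau = np.ones((12, 1))
        p = m_step(X, Y, tau, "gaussian_regression")
        iu = np.triu_indices(12, 1)
        A = np.column_stack([np.ones(iu[0].size), Y[0][iu]])
        coef = np.linalg.solve(A.T @ A, A.T @ X[iu])  # normal equations oracle
        assert p.mu[0, 0] == pytest.approx(coef[0], abs=1e-6)
        assert p.beta[0, 0, 0] == pytest.approx(coef[1], abs=1e-6)

    def test_hard_tau_bernoulli_gives_block_densities(self):
        rng = np.random.default_rng(4)
        Z = (random_symmetric(rng, 10) > 0.6).astype(float)
        labels = np.array([0] * 5 + [1] * 5)
        tau = np.eye(2)[labels]
        p = m_step(Z, None, tau, "bernoulli")
        in0 = Z[np.ix_(labels == 0, labels == 0)][np.triu_indices(5, 1)].mean()
        cross = Z[np.ix_(labels == 0, labels == 1)].mean()
        assert p.mu[0, 0] == pytest.approx(in0, abs=1e-9)
        assert p.mu[0, 1] == pytest.approx(cross, abs=1e-9)

    def test_cluster_pair_matrices_are_symmetric(self):
        rng = np.random.default_rng(5)
        X = random_symmetric(rng, 15)
        Y = np.stack([random_symmetric(rng, 15), random_symmetric(rng, 15)])
        tau = rng.dirichlet(np.ones(3), size=15)
        p = m_step(X, Y, tau, "gaussian_regression")
        assert np.array_equal(p.mu, p.mu.T)
        for k in range(2):
            assert np.array_equal(p.beta[:, :, k], p.beta[:, :, k].T)


class TestLowerBound:
    def test_single_cluster_reduces_to_edge_loglik(self):
        rng = np.random.default_rng(6)
        X = random_symmetric(rng, 8)
        params = _gaussian_params([1.0], [[0.4]], 0.2)
        tau = np.ones((8, 1))
        iu = np.triu_indices(8, 1)
        direct = sum(-0.5 * math.log(2 * math.pi * 0.2)
                     - (x - 0.4) ** 2 / (2 * 0.2) for x in X[iu])
        assert lower_bound(X, None, params, tau) == pytest.approx(direct, rel=1e-12)

    def test_hard_tau_equals_complete_data_loglik(self):
        rng = np.random.default_rng(7)
        X = random_symmetric(rng, 9)
        labels = np.array([0, 0, 0, 1, 1, 1, 1, 0, 1])
        tau = np.eye(2)[labels]
        params = _gaussian_params([4 / 9, 5 / 9], [[0.3, 0.6], [0.6, 0.8]], 0.1)
        direct = sum(math.log(params.alpha[q]) for q in labels)
        for i, j in itertools.combinations(range(9), 2):
            mu = params.mu[labels[i], labels[j]]
            direct += (-0.5 * math.log(2 * math.pi * 0.1)
                       - (X[i, j] - mu) ** 2 / (2 * 0.1))
        assert lower_bound(X, None, params, tau) == pytest.approx(direct, rel=1e-12)

    def test_converged_tau_is_locally_optimal(self):
        s = simulate_blockmodel_graph(_cfg(n=20, Q=2, mu=(0.8, 0.2), sigma=0.1,
                                           seed=8))
        fit = fit_blockmodel(s.network.X, family="gaussian", Q=2, n_restarts=3,
                             random_state=0)
        J0 = lower_bound(s.network.X, None, fit.params, fit.tau)
        rng = np.random.default_rng(9)
        for _ in range(10):
            bump = fit.tau + 0.02 * rng.dirichlet(np.ones(2), size=20)
            bump /= bump.sum(1, keepdims=True)
            assert lower_bound(s.network.X, None, fit.params, bump) <= J0 + 1e-9


class TestFit:
    def test_planted_partition_recovered(self):
        s = simulate_blockmodel_graph(_cfg(n=60, Q=3, mu=(0.9, 0.3), sigma=0.1,
                                           seed=7))
        fit = fit_blockmodel(s.network.X, family="gaussian", Q=3, n_restarts=3,
                             random_state=1)
        assert partition_match(fit.labels, s.labels) == (100, 60)

    def test_null_covariate_yields_near_zero_beta(self):
        s = simulate_blockmodel_graph(_cfg(n=60, Q=3, mu=(0.9, 0.3), sigma=0.1,
                                           seed=7))
        cov = simulate_covariates(s.labels, 0.5, 0.5, 0.2, seed=10)
        fit = fit_blockmodel(s.network.X, cov, family="gaussian_regression",
                             Q=3, n_restarts=3, random_state=1)
        assert np.all(np.abs(fit.params.beta) < 0.1)

    def test_model_nesting_in_q(self):
        s = simulate_blockmodel_graph(_cfg(n=12, Q=2, mu=(0.8, 0.2), sigma=0.1,
                                           seed=3))
        X = s.network.X
        J_small = fit_blockmodel(X, family="gaussian", Q=2, n_restarts=3,
                                 random_state=0).J
        J_full = fit_blockmodel(X, family="gaussian", Q=12, n_restarts=3,
                                random_state=0).J
        assert J_full >= J_small - 1e-6

    def test_zero_covariates_reproduce_gaussian_fit(self):
        s = simulate_blockmodel_graph(_cfg(n=30, Q=2, mu=(0.8, 0.2), sigma=0.1,
                                           seed=5))
        X = s.network.X
        plain = fit_blockmodel(X, family="gaussian", Q=2, n_restarts=3,
                               random_state=2)
        null = fit_blockmodel(X, np.zeros((1, 30, 30)),
                              family="gaussian_regression", Q=2, n_restarts=3,
                              random_state=2)
        assert null.J == pytest.approx(plain.J, abs=1e-6)

    def test_bernoulli_rejects_covariates(self):
        with pytest.raises(ValueError):
            fit_blockmodel(np.zeros((4, 4)), np.zeros((1, 4, 4)),
                           family="bernoulli", Q=1)

    def test_deterministic_given_seed(self):
        s = simulate_blockmodel_graph(_cfg(n=20, Q=2, mu=(0.8, 0.2), sigma=0.1,
                                           seed=6))
        a = fit_blockmodel(s.network.X, family="gaussian", Q=2, n_restarts=4,
                           random_state=5)
        b = fit_blockmodel(s.network.X, family="gaussian", Q=2, n_restarts=4,
                           random_state=5)
        assert a.J == b.J and np.array_equal(a.tau, b.tau)

    def test_em_matches_exhaustive_enumeration(self):
        # complete-data log-likelihood oracle over all 2^n labelings
        s = simulate_blockmodel_graph(_cfg(n=8, Q=2, mu=(0.9, 0.2), sigma=0.08,
                                           seed=12))
        X = s.network.X
        best = -np.inf
        for bits in itertools.product([0, 1], repeat=8):
            tau = np.eye(2)[list(bits)]
            params = m_step(X, None, tau, "gaussian")
            best = max(best, lower_bound(X, None, params, tau))
        fit = fit_blockmodel(X, family="gaussian", Q=2, n_restarts=8,
                             random_state=3)
        hard = np.eye(2)[fit.labels]
        params = m_step(X, None, hard, "gaussian")
        J_hard = lower_bound(X, None, params, hard)
        assert J_hard == pytest.approx(best, abs=1e-6)


class TestICL:
    def test_q1_penalties_vanish_at_n2(self):
        assert icl_score(-3.21, n=2, Q=1, d=0) == -3.21

    @pytest.mark.parametrize("Q, d, expected", [
        (4, 1, 35),   # (Q-1) + Q^2 (d+1)
        (1, 0, 1),
        (3, 2, 29),
        (6, 0, 41),
    ])
    def test_parameter_count(self, Q, d, expected):
        assert n_parameters(Q, d) == expected

    def test_one_extra_covariate_adds_q_squared_parameters(self):
        for Q in range(1, 7):
            assert n_parameters(Q, 2) - n_parameters(Q, 1) == Q * Q

    def test_jeffreys_flag(self):
        assert JEFFREYS_THRESHOLD == pytest.approx(math.log(100))
        assert jeffreys_substantial(0.0, -5.0)
        assert not jeffreys_substantial(0.0, -4.0)

    def test_penalty_formula(self):
        n, Q, d, J = 46, 4, 1, -270.0
        expected = (J - (Q - 1) / 2 * math.log(n)
                    - Q * Q * (d + 1) / 2 * math.log(n * (n - 1) / 2))
        assert icl_score(J, n, Q, d) == pytest.approx(expected, rel=1e-12)


@pytest.fixture(scope="module")
def planted():
    s = simulate_blockmodel_graph(_cfg(n=50, Q=3, mu=(0.9, 0.3), sigma=0.1,
                                       seed=21))
    table, fits = model_scan(s.network.X, family="gaussian",
                             Q_range=range(1, 6), n_restarts=3,
                             random_state=0)
    return s, table, fits


class TestScan:
    def test_selects_planted_q(self, planted):
        s, table, fits = planted
        assert int(table.loc[table["best"], "Q"].iloc[0]) == 3

    def test_posterior_probabilities_sum_to_one(self, planted):
        _, table, _ = planted
        assert table["post_proba"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_q_scan_has_probability_one(self):
        rng = np.random.default_rng(0)
        X = random_symmetric(rng, 10)
        table, _ = model_scan(X, family="gaussian", Q_range=[2], n_restarts=2,
                              random_state=0)
        assert table["post_proba"].iloc[0] == pytest.approx(1.0)


class TestEstimatorAPI:
    def test_fit_sets_sklearn_style_attributes(self):
        s = simulate_blockmodel_graph(_cfg(n=24, Q=2, mu=(0.8, 0.2), sigma=0.1,
                                           seed=2))
        est = NetworkBlockModel(family="gaussian", n_clusters=2, n_restarts=3,
                                random_state=0)
        est.fit(s.network.X)
        assert est.weights_.shape == (2,)
        assert est.means_.shape == (2, 2)
        assert est.responsibilities_.shape == (24, 2)
        assert np.allclose(est.responsibilities_.sum(1), 1.0, atol=1e-9)
        assert est.labels_.shape == (24,)
        assert est.icl_ < est.lower_bound_
        assert est.score() == est.lower_bound_

    def test_clone_and_params_roundtrip(self):
        est = NetworkBlockModel(family="bernoulli", n_clusters=4, random_state=7)
        twin = clone(est)
        assert twin.get_params() == est.get_params()
        twin.set_params(n_clusters=2)
        assert twin.n_clusters == 2 and est.n_clusters == 4

    def test_fit_predict_returns_labels(self):
        s = simulate_blockmodel_graph(_cfg(n=20, Q=2, mu=(0.9, 0.1), sigma=0.05,
                                           seed=13))
        labels = NetworkBlockModel(family="gaussian", n_clusters=2, n_restarts=3,
                                   random_state=0).fit_predict(s.network.X)
        assert partition_match(labels, s.labels)[0] == 100
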