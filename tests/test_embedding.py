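import numpy as np
import pytest
from scipy import optimize

from cellmix import (
    BulkExpression,
    EmbeddingConfig,
    expected_assignments,
    fit_embedding,
    nmf_init,
)


def _bulk(X):
    X = np.asarray(X)
    return BulkExpression(
        X=X,
        sample_ids=[f"s{i}" for i in range(X.shape[0])],
        gene_ids=np.array([f"g{i}" for i in range(X.shape[1])], dtype=object),
    )


def _disjoint_bases(G, K=2, rng=None):
    rng = rng or np.random.default_rng(0)
    eta = np.zeros((K, G))
    block = G // K
    for k in range(K):
        sl = slice(k * block, (k + 1) * block if k < K - 1 else G)
        vals = rng.random(sl.stop - sl.start) + 0.05
        eta[k, sl] = vals / vals.sum()
    return eta


def _match_rows(est, true):
    """Greedy row matching by cosine similarity; returns per-row cosines."""
    sims = np.zeros(true.shape[0])
    used = set()
    for i in range(true.shape[0]):
        best, best_j = -1.0, None
        for j in range(est.shape[0]):
            if j in used:
                continue
            c = est[j] @ true[i] / (np.linalg.norm(est[j]) * np.linalg.norm(true[i]))
            if c > best:
                best, best_j = c, j
        sims[i] = best
        used.add(best_j)
    return sims


def _planted_instance(seed, N=50, G=200, depth=100_000, env_frac=0.3):
    """K=2 disjoint-support programs plus one fixed environment type."""
    rng = np.random.default_rng(seed)
    eta_true = _disjoint_bases(G, 2, rng)
    psi_env = rng.dirichlet(np.ones(G))[None, :]
    theta_env = np.full((N, 1), env_frac)
    tau = 1.0 - theta_env[:, 0]
    kappa = rng.dirichlet([1.0, 1.0], size=N)
    omega_true = kappa * tau[:, None]
    upsilon = np.hstack([omega_true, theta_env])
    zeta = np.vstack([eta_true, psi_env])
    mix = upsilon @ zeta
    X = np.vstack([rng.multinomial(depth, m) for m in mix])
    return _bulk(X), theta_env, psi_env, eta_true, omega_true


class TestNMFInit:
    def test_recovers_planted_rank_two_structure(self):
        bulk, _, _, eta_true, omega_true = _planted_instance(1, env_frac=0.0)
        Z_norm = bulk.X / bulk.X.sum(axis=1, keepdims=True)
        cfg = EmbeddingConfig(k_grid=(2, 3, 4), n_consensus_runs=10,
                              n_nmf_restarts=20, seed=0)
        eta0, K, scores = nmf_init(Z_norm, cfg)
        assert K == 2
        assert set(scores) == {2, 3, 4}
        sims = _match_rows(eta0, eta_true)
        assert sims.min() > 0.99

    def test_rank_one_residual_dominates_rank_two(self):
        bulk, *_ = _planted_instance(2, env_frac=0.0)
        Z_norm = bulk.X / bulk.X.sum(axis=1, keepdims=True)
        from cellmix.embedding import _nmf_fit

        r1 = _nmf_fit(Z_norm, 1, 0, 400).reconstruction_err_
        r2 = _nmf_fit(Z_norm, 2, 0, 400).reconstruction_err_
        assert r1 >= r2

    def test_deterministic_under_fixed_seed(self):
        bulk, *_ = _planted_instance(3, env_frac=0.0)
        Z_norm = bulk.X / bulk.X.sum(axis=1, keepdims=True)
        cfg = EmbeddingConfig(K=2, n_nmf_restarts=5, seed=4)
        a, _, _ = nmf_init(Z_norm, cfg)
        b, _, _ = nmf_init(Z_norm, cfg)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_dimensions_errors(self):
        Z = np.random.default_rng(0).random((4, 10))
        with pytest.raises(ValueError, match="exceeds"):
            nmf_init(Z, EmbeddingConfig(K=5))
        with pytest.raises(ValueError, match="exceeds"):
            nmf_init(Z, EmbeddingConfig(k_grid=(2, 5)))


class TestFitEmbedding:
    def test_pure_tumour_single_basis_limit(self):
        # T-1 = 0, K = 1, diffuse prior: eta approaches pooled normalized counts
        rng = np.random.default_rng(5)
        X = rng.integers(0, 50, size=(4, 6)) + 1
        bulk = _bulk(X)
        eta0 = np.full((1, 6), 1 / 6)
        cfg = EmbeddingConfig(K=1, sigma=100.0, em_max_iter=200)
        res = fit_embedding(bulk, np.zeros((4, 0)), np.zeros((0, 6)), eta0, cfg)
        np.testing.assert_allclose(res.omega[:, 0], 1.0, atol=1e-9)
        pooled = X.sum(axis=0) / X.sum()
        np.testing.assert_allclose(res.eta[0], pooled, atol=1e-3)

    def test_planted_recovery(self):
        bulk, theta_env, psi_env, eta_true, omega_true = _planted_instance(11)
        cfg = EmbeddingConfig(K=2, seed=0, em_max_iter=100)
        # initialize from a perturbed truth, as NMF would supply
        rng = np.random.default_rng(1)
        eta0 = eta_true * np.exp(0.3 * rng.standard_normal(eta_true.shape)) + 1e-8
        eta0 = eta0 / eta0.sum(axis=1, keepdims=True)
        res = fit_embedding(bulk, theta_env, psi_env, eta0, cfg)
        sims = _match_rows(res.eta, eta_true)
        assert sims.min() > 0.95
        order = np.argsort(
            [-np.corrcoef(res.eta[j], eta_true[0])[0, 1] for j in range(2)]
        )
        for k in range(2):
            r = np.corrcoef(res.omega[:, order[k]], omega_true[:, k])[0, 1]
            assert r > 0.95

    def test_log_posterior_monotone_and_omega_sums_to_tau(self):
        bulk, theta_env, psi_env, eta_true, _ = _planted_instance(12, N=10, G=50,
                                                                  depth=5000)
        eta0 = np.full((2, 50), 1 / 50)
        res = fit_embedding(bulk, theta_env, psi_env, eta0,
                            EmbeddingConfig(K=2, em_max_iter=50))
        diffs = np.diff(res.log_posterior_trace)
        scale = np.maximum(1.0, np.abs(res.log_posterior_trace[:-1]))
        assert (diffs >= -1e-8 * scale).all()
        np.testing.assert_allclose(res.omega.sum(axis=1), res.tau, atol=1e-6)

    def test_fixed_blocks_untouched(self):
        bulk, theta_env, psi_env, *_ = _planted_instance(13, N=8, G=40, depth=5000)
        theta_copy, psi_copy = theta_env.copy(), psi_env.copy()
        fit_embedding(bulk, theta_env, psi_env, np.full((2, 40), 1 / 40),
                      EmbeddingConfig(K=2, em_max_iter=20))
        np.testing.assert_array_equal(theta_env, theta_copy)
        np.testing.assert_array_equal(psi_env, psi_copy)

    def test_nonpositive_tau_errors(self):
        bulk = _bulk(np.ones((2, 3), dtype=int))
        theta_env = np.array([[0.6, 0.5], [0.3, 0.3]])  # first sample sums > 1
        psi_env = np.full((2, 3), 1 / 3)
        with pytest.raises(ValueError, match="tau"):
            fit_embedding(bulk, theta_env, psi_env, np.full((1, 3), 1 / 3),
                          EmbeddingConfig(K=1))

    def test_matches_direct_numerical_map_on_tiny_instance(self):
        # N=2, G=3, K=1, one environment type: with K=1 omega is fixed at tau,
        # so the EM optimum must agree with direct maximization over eta.
        X = np.array([[30, 10, 5], [12, 25, 8]])
        bulk = _bulk(X)
        theta_env = np.array([[0.4], [0.3]])
        psi_env = np.array([[0.2, 0.3, 0.5]])
        eta0 = np.array([[1 / 3, 1 / 3, 1 / 3]])
        sigma = 2.0
        res = fit_embedding(bulk, theta_env, psi_env, eta0,
                            EmbeddingConfig(K=1, sigma=sigma, em_max_iter=500,
                                            em_tol=1e-12))

        tau = 1.0 - theta_env[:, 0]

        def neg_log_post(log_lam):
            w = eta0[0] * np.exp(log_lam)
            eta = w / w.sum()
            mix = tau[:, None] * eta[None, :] + theta_env @ psi_env
            ll = np.sum(X * np.log(mix))
            return -(ll - np.sum(log_lam**2) / (2 * sigma**2))

        direct = optimize.minimize(neg_log_post, np.zeros(3), method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 10_000})
        w = eta0[0] * np.exp(direct.x)
        eta_direct = w / w.sum()
        np.testing.assert_allclose(res.eta[0], eta_direct, atol=1e-4)


def test_expected_assignments_conserve_reads():
    rng = np.random.default_rng(7)
    N, M, G = 3, 4, 5
    upsilon = rng.dirichlet(np.ones(M), size=N)
    zeta = rng.dirichlet(np.ones(G), size=M)
    X = rng.integers(1, 100, size=(N, G)).astype(float)
    V = expected_assignments(X, upsilon, zeta)
    np.testing.assert_allclose(V.sum(axis=1), X, rtol=1e-12)
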