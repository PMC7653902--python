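import numpy as np
import pytest

from dtimdn import (
    HeteroNetwork,
    MDMConfig,
    MDMModel,
    ValidationError,
    build_network,
    corrupt,
    default_latent_dim,
    dti_scores,
    fit,
    loss_gradient,
    marginalized_loss,
    reconstruct,
)
from dtimdn.mdm import (
    OptimizationError,
    exp_pair_term,
    exp_pair_term_outer,
    exp_triple_term,
    exp_quartic_trace,
    load_model,
    save_model,
)

from .conftest import make_random_network
from .oracles import (
    enum_corruption_expect,
    mc_corruption_expect,
    transcribed_reconstruction,
)


class TestBuildNetwork:
    def test_block_layout(self):
        m, n = 2, 3
        KFJT = np.arange(4, dtype=float).reshape(2, 2)
        KFJT = 0.5 * (KFJT + KFJT.T)
        KFJD = np.eye(3)
        Y = np.arange(6, dtype=float).reshape(3, 2)
        net = build_network(KFJT, KFJD, Y)
        assert net.M.shape == (5, 5)
        np.testing.assert_array_equal(net.M[0:2, 2:5], Y.T)
        np.testing.assert_array_equal(net.M[2:5, 0:2], Y)
        np.testing.assert_array_equal(net.M[:2, :2], KFJT)
        np.testing.assert_array_equal(net.M[2:, 2:], KFJD)

    def test_symmetry(self):
        net = build_network(np.eye(2), np.eye(3),
                            np.ones((3, 2)))
        assert np.array_equal(net.M, net.M.T)

    def test_zero_interactions_block_diagonal(self):
        net = build_network(np.eye(2), np.eye(3), np.zeros((3, 2)))
        assert np.all(net.M[0:2, 2:5] == 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            build_network(np.eye(2), np.eye(3), np.zeros((2, 3)))


class TestCorrupt:
    @pytest.fixture()
    def net(self):
        return HeteroNetwork(make_random_network(10, 0), m=4, n=6)

    def test_deterministic(self, net):
        a = corrupt(net, 0.65, seed=5)
        b = corrupt(net, 0.65, seed=5)
        assert np.array_equal(a.M_tilde, b.M_tilde)

    def test_entries_kept_or_zeroed(self, net):
        s = corrupt(net, 0.5, seed=1)
        same = s.M_tilde == net.M
        zeroed = s.M_tilde == 0.0
        assert np.all(same | zeroed)

    def test_tiny_p_keeps_everything(self, net):
        s = corrupt(net, 1e-9, seed=2)
        assert np.array_equal(s.M_tilde, net.M)

    def test_zeroed_fraction_binomial(self):
        net = HeteroNetwork(make_random_network(50, 3), m=20, n=30)
        s = corrupt(net, 0.65, seed=7)
        frac = np.mean(s.M_tilde[net.M != 0] == 0.0)
        n_cells = int((net.M != 0).sum())
        sd = np.sqrt(0.65 * 0.35 / n_cells)
        assert abs(frac - 0.65) <= 4 * sd

    def test_p_out_of_range(self, net):
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValidationError):
                corrupt(net, p, seed=0)


QS = (0.2, 0.35, 0.5, 0.8)


class TestExpectationClosedForms:
    """The closed forms must equal the exhaustive corruption expectation."""

    def test_pair_no_corruption_limit(self):
        rng = np.random.default_rng(0)
        M, C = rng.normal(size=(3, 2)), rng.normal(size=(3, 3))
        np.testing.assert_allclose(exp_pair_term(M, C, 1.0), M.T @ C @ M,
                                   atol=1e-12)
        np.testing.assert_allclose(exp_pair_term(M, C, 0.0), 0.0, atol=1e-15)

    def test_pair_scalar_case(self):
        m, c, q = 1.7, -0.3, 0.35
        # E[m_tilde^2] = q m^2, so the expectation is q*c*m^2
        got = exp_pair_term(np.array([[m]]), np.array([[c]]), q)
        assert got[0, 0] == pytest.approx(q * c * m * m, abs=1e-15)

    @pytest.mark.parametrize("q", QS)
    @pytest.mark.parametrize("shape", [(2, 2), (3, 2)])
    def test_pair_matches_enumeration(self, q, shape):
        rng = np.random.default_rng(hash((q, shape)) % 2**31)
        M = rng.normal(size=shape)
        C = rng.normal(size=(shape[0], shape[0]))
        expected = enum_corruption_expect(M, q, lambda Mt: Mt.T @ C @ Mt)
        np.testing.assert_allclose(exp_pair_term(M, C, q), expected,
                                   atol=1e-12)
        Co = rng.normal(size=(shape[1], shape[1]))
        expected = enum_corruption_expect(M, q, lambda Mt: Mt @ Co @ Mt.T)
        np.testing.assert_allclose(exp_pair_term_outer(M, Co, q), expected,
                                   atol=1e-12)

    @pytest.mark.parametrize("q", QS)
    @pytest.mark.parametrize("n", [2, 3])
    def test_triple_matches_enumeration(self, q, n):
        rng = np.random.default_rng(100 + n)
        M = rng.normal(size=(n, n))
        C = rng.normal(size=(n, n))
        expected = enum_corruption_expect(M, q,
                                          lambda Mt: Mt @ C @ Mt.T @ Mt.T)
        np.testing.assert_allclose(exp_triple_term(M, C, q), expected,
                                   atol=1e-12)

    def test_triple_limits(self):
        rng = np.random.default_rng(4)
        M, C = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        np.testing.assert_allclose(exp_triple_term(M, C, 1.0),
                                   M @ C @ M.T @ M.T, atol=1e-12)
        np.testing.assert_allclose(exp_triple_term(M, C, 0.0), 0.0,
                                   atol=1e-15)

    @pytest.mark.parametrize("q", QS)
    @pytest.mark.parametrize("n", [2, 3])
    def test_quartic_matches_enumeration(self, q, n):
        rng = np.random.default_rng(200 + n)
        M = rng.normal(size=(n, n))
        C = rng.normal(size=(n, n))
        C = C + C.T
        expected = enum_corruption_expect(
            M, q, lambda Mt: np.trace(Mt @ C @ Mt.T @ Mt @ C @ Mt.T))
        got = exp_quartic_trace(M, C, q)
        assert got == pytest.approx(float(expected), rel=1e-12, abs=1e-12)

    def test_monte_carlo_agreement_5x5(self):
        rng = np.random.default_rng(9)
        M = rng.random((5, 5))  # nonnegative, like the network M
        C = rng.random((5, 5))
        q = 0.35
        mc = mc_corruption_expect(M, q, lambda Mt: Mt @ C @ Mt.T @ Mt.T,
                                  n_samples=20000, seed=13)
        closed = exp_triple_term(M, C, q)
        rel = np.linalg.norm(mc - closed) / np.linalg.norm(closed)
        assert rel < 0.05


class TestMarginalizedLoss:
    def _setup(self, d=6, k=2, seed=0, noise=0.65):
        rng = np.random.default_rng(seed)
        net = HeteroNetwork(make_random_network(d, seed), m=d // 2,
                            n=d - d // 2)
        cfg = MDMConfig(noise=noise, latent_dim=k, lambda1=0.013,
                        lambda2=0.007)
        model = MDMModel(rng.normal(size=(d, k)), rng.normal(size=(d, k)),
                         rng.normal(size=d), cfg)
        return model, net, cfg

    def test_zero_model_anchor(self):
        _, net, cfg = self._setup()
        d = net.size
        model = MDMModel(np.zeros((d, 2)), np.zeros((d, 2)), np.zeros(d), cfg)
        assert marginalized_loss(model, net, cfg) == pytest.approx(
            0.5 * np.trace(net.M.T @ net.M), rel=1e-14)

    def test_zero_network_anchor(self):
        model, net, cfg = self._setup()
        zero_net = HeteroNetwork(np.zeros_like(net.M), net.m, net.n)
        model.b = np.zeros(net.size)
        expected = 0.5 * cfg.lambda1 * np.sum(model.U ** 2) \
            + 0.5 * cfg.lambda2 * np.sum(model.V ** 2)
        assert marginalized_loss(model, zero_net, cfg) == pytest.approx(
            expected, rel=1e-14)

    @pytest.mark.parametrize("q", (0.35, 0.8))
    def test_matches_enumeration_3x3(self, q):
        rng = np.random.default_rng(21)
        d, k = 3, 2
        net = HeteroNetwork(make_random_network(d, 21), m=1, n=2)
        cfg = MDMConfig(noise=1 - q, latent_dim=k, lambda1=0.013,
                        lambda2=0.007)
        U, V = rng.normal(size=(d, k)), rng.normal(size=(d, k))
        b = rng.normal(size=d)
        model = MDMModel(U, V, b, cfg)
        L, G = U @ U.T, V @ V.T

        def raw(Mt):
            R = net.M - L @ Mt - Mt @ G @ Mt.T - b[:, None]
            return np.sum(R * R)

        expected = 0.5 * enum_corruption_expect(net.M, q, raw) \
            + 0.5 * cfg.lambda1 * np.sum(U * U) \
            + 0.5 * cfg.lambda2 * np.sum(V * V)
        got = marginalized_loss(model, net, cfg)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_matches_monte_carlo_6x6(self):
        model, net, cfg = self._setup(d=6, k=2, seed=5)
        L, G, b = model.local_weights, model.global_weights, model.b

        def raw(Mt):
            R = net.M - L @ Mt - Mt @ G @ Mt.T - b[:, None]
            return np.sum(R * R)

        mc = 0.5 * mc_corruption_expect(net.M, cfg.q, raw,
                                        n_samples=100_000, seed=3)
        mc += 0.5 * cfg.lambda1 * np.sum(model.U ** 2) \
            + 0.5 * cfg.lambda2 * np.sum(model.V ** 2)
        got = marginalized_loss(model, net, cfg)
        assert got == pytest.approx(float(mc), rel=0.01)

    def test_q_one_equals_uncorrupted_loss(self):
        model, net, _ = self._setup()
        cfg = MDMConfig(noise=1e-12, latent_dim=2, lambda1=0.013,
                        lambda2=0.007)
        L, G, b = model.local_weights, model.global_weights, model.b
        R = net.M - L @ net.M - net.M @ G @ net.M.T - b[:, None]
        expected = 0.5 * np.sum(R * R) \
            + 0.5 * cfg.lambda1 * np.sum(model.U ** 2) \
            + 0.5 * cfg.lambda2 * np.sum(model.V ** 2)
        assert marginalized_loss(model, net, cfg) == pytest.approx(
            expected, rel=1e-9)


class TestLossGradient:
    def test_regularizer_only(self):
        d, k = 5, 2
        rng = np.random.default_rng(0)
        net = HeteroNetwork(np.zeros((d, d)), m=2, n=3)
        cfg = MDMConfig(noise=0.65, latent_dim=k, lambda1=0.3, lambda2=0.2)
        model = MDMModel(rng.normal(size=(d, k)), rng.normal(size=(d, k)),
                         np.zeros(d), cfg)
        gU, gV, gb = loss_gradient(model, net, cfg)
        np.testing.assert_allclose(gU, cfg.lambda1 * model.U, atol=1e-14)
        np.testing.assert_allclose(gV, cfg.lambda2 * model.V, atol=1e-14)
        np.testing.assert_allclose(gb, 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_finite_difference_agreement(self, seed):
        d, k = 8, 3
        rng = np.random.default_rng(1000 + seed)
        net = HeteroNetwork(make_random_network(d, seed), m=3, n=5)
        cfg = MDMConfig(noise=0.65, latent_dim=k)
        model = MDMModel(rng.normal(size=(d, k)), rng.normal(size=(d, k)),
                         rng.normal(size=d), cfg)
        gU, gV, gb = loss_gradient(model, net, cfg)
        eps = 1e-6
        for arr, grad in ((model.U, gU), (model.V, gV), (model.b, gb)):
            flat = arr.ravel()
            num = np.zeros_like(flat)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = marginalized_loss(model, net, cfg)
                flat[i] = orig - eps
                lm = marginalized_loss(model, net, cfg)
                flat[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            rel = np.max(np.abs(num - grad.ravel())) \
                / max(1e-12, np.max(np.abs(num)))
            assert rel < 1e-4


class TestFit:
    def test_null_network_converges_to_zero(self):
        net = HeteroNetwork(np.zeros((6, 6)), m=3, n=3)
        cfg = MDMConfig(noise=0.65, latent_dim=2, seed=0)
        model = fit(net, cfg)
        assert model.final_loss < 1e-3
        assert np.max(np.abs(model.b)) < 1e-2

    def test_deterministic_given_seed(self):
        net = HeteroNetwork(make_random_network(10, 2), m=4, n=6)
        cfg = MDMConfig(noise=0.65, latent_dim=3, seed=7, max_iters=30)
        a, b = fit(net, cfg), fit(net, cfg)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.b, b.b)

    def test_loss_decreases_on_planted_network(self, block_dataset):
        from dtimdn.kernels import build_final_kernels

        kfjd, kfjt = build_final_kernels(block_dataset)
        net = build_network(kfjt, kfjd, block_dataset.Y_filled)
        cfg = MDMConfig(noise=0.65, latent_dim=8, seed=1, max_iters=60)
        model = fit(net, cfg)
        assert model.final_loss < 0.5 * model.initial_loss

    def test_non_finite_loss_aborts_with_iteration(self):
        M = np.full((4, 4), 1e200)  # loss overflows at the first evaluation
        net = HeteroNetwork(M, m=2, n=2)
        cfg = MDMConfig(noise=0.65, latent_dim=2, seed=0)
        with np.errstate(all="ignore"):
            with pytest.raises(OptimizationError, match="evaluation"):
                fit(net, cfg)

    def test_latent_dim_validation(self):
        net = HeteroNetwork(np.zeros((4, 4)), m=2, n=2)
        with pytest.raises(ValidationError):
            fit(net, MDMConfig(latent_dim=5))

    def test_default_latent_dim_rule(self):
        assert default_latent_dim(445) == 100
        assert default_latent_dim(54) == 20
        assert default_latent_dim(240) == 60


class TestReconstructAndScores:
    def test_zero_factors_rows_constant_at_bias(self):
        d = 5
        net = HeteroNetwork(make_random_network(d, 0), m=2, n=3)
        b = np.arange(d, dtype=float)
        model = MDMModel(np.zeros((d, 2)), np.zeros((d, 2)), b, MDMConfig())
        M_star = reconstruct(model, net)
        np.testing.assert_array_equal(M_star, np.tile(b[:, None], (1, d)))

    def test_identity_local_weights_reproduce_network(self):
        d = 4
        net = HeteroNetwork(make_random_network(d, 1), m=2, n=2)
        model = MDMModel(np.eye(d), np.zeros((d, d)), np.zeros(d),
                         MDMConfig(latent_dim=d))
        np.testing.assert_allclose(reconstruct(model, net), net.M, atol=1e-12)

    def test_matches_transcription(self):
        d, k = 5, 2
        rng = np.random.default_rng(8)
        net = HeteroNetwork(make_random_network(d, 8), m=2, n=3)
        U, V = rng.normal(size=(d, k)), rng.normal(size=(d, k))
        b = rng.normal(size=d)
        model = MDMModel(U, V, b, MDMConfig(latent_dim=k))
        expected = transcribed_reconstruction(U, V, b, net.M)
        np.testing.assert_allclose(reconstruct(model, net), expected,
                                   atol=1e-12)

    def test_scores_average_the_two_blocks(self):
        m, n = 2, 3
        net = build_network(np.eye(m), np.eye(n), np.zeros((n, m)))
        M_star = np.arange(25, dtype=float).reshape(5, 5)
        s = dti_scores(M_star, net)
        assert s.shape == (n, m)
        expected = 0.5 * (M_star[m:, :m] + M_star[:m, m:].T)
        np.testing.assert_array_equal(s, expected)
        sym = 0.5 * (M_star + M_star.T)
        np.testing.assert_allclose(dti_scores(sym, net), sym[m:, :m])


class TestModelSerialization:
    def test_round_trip(self, tmp_path):
        net = HeteroNetwork(make_random_network(8, 3), m=3, n=5)
        cfg = MDMConfig(noise=0.65, latent_dim=2, seed=3, max_iters=10)
        model = fit(net, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path, entity_ids=list("abcdefgh"))
        loaded, ids = load_model(path)
        assert ids == list("abcdefgh")
        np.testing.assert_array_equal(loaded.U, model.U)
        np.testing.assert_array_equal(loaded.b, model.b)
        assert loaded.config == model.config
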