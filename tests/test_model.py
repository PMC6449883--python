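"""Model forward pass, negative-sampling loss, gradients and training."""

import copy
import math

import numpy as np
import pytest

import gne
from gne.model import (
    Adam,
    NoiseSampler,
    init_params,
    loss_and_grads,
    zero_grads,
)


def small_hyper(**kw):
    base = dict(d=3, k=1, lam=0.7, num_neg=2, seed=0)
    base.update(kw)
    return gne.GNEHyper(**base)


class TestInitParams:
    def test_shapes(self):
        h = gne.GNEHyper(d=2, k=1)
        p = init_params(h, M=3, E=2, seed=0)
        assert p.W_id.shape == (2, 3)
        assert p.W_att.shape == (2, 2)
        assert p.hidden[0].W.shape == (2, 4)
        assert p.W_out.shape == (3, 2)

    def test_deterministic(self):
        h = small_hyper()
        a = init_params(h, 5, 3, seed=4)
        b = init_params(h, 5, 3, seed=4)
        for (_, x), (_, y) in zip(a.trainable(), b.trainable()):
            assert np.array_equal(x, y)

    def test_no_expression_mode(self):
        h = small_hyper()
        p = init_params(h, 4, 0, seed=0)
        assert p.W_att.shape == (3, 0)
        v_a = gne.transform_attributes(p, np.zeros(0))
        assert np.all(v_a == 0.0)

    def test_deeper_stack_widths(self):
        p = init_params(gne.GNEHyper(d=4, k=3), 5, 2, seed=0)
        assert [l.W.shape for l in p.hidden] == [(4, 8), (4, 4), (4, 4)]


class TestForwardPieces:
    def test_lookup_is_one_hot_column(self):
        h = gne.GNEHyper(d=2)
        p = init_params(h, 2, 0, seed=0)
        p.W_id = np.eye(2)
        assert np.array_equal(gne.lookup_structure(p, 0), [1.0, 0.0])
        p.W_id = np.array([[1.0, 3.0], [2.0, 4.0]])
        assert np.array_equal(gne.lookup_structure(p, 1), [3.0, 4.0])

    def test_lookup_matches_dense_product(self):
        p = init_params(gne.GNEHyper(d=4), 6, 0, seed=1)
        for i in range(6):
            one_hot = np.zeros(6)
            one_hot[i] = 1.0
            assert np.allclose(gne.lookup_structure(p, i), p.W_id @ one_hot)

    def test_lookup_out_of_range(self):
        p = init_params(gne.GNEHyper(d=2), 3, 0, seed=0)
        with pytest.raises(IndexError):
            gne.lookup_structure(p, 3)

    def test_attribute_transform_elu_closed_form(self):
        p = init_params(gne.GNEHyper(d=2), 3, 2, seed=0)
        p.W_att = np.array([[1.0, 0.0], [0.0, -1.0]])
        assert np.all(gne.transform_attributes(p, np.zeros(2)) == 0.0)
        out = gne.transform_attributes(p, np.array([1.0, 1.0]))  # W x = [1, -1]
        assert np.allclose(out, [1.0, math.exp(-1) - 1], atol=1e-12)

    def test_attribute_transform_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        p = init_params(gne.GNEHyper(d=5), 3, 7, seed=3)
        x = rng.normal(size=7)
        z = p.W_att @ x
        oracle = np.array([zi if zi > 0 else math.expm1(zi) for zi in z])
        assert np.allclose(gne.transform_attributes(p, x), oracle, atol=1e-12)

    def test_fuse_scaling_and_limits(self):
        assert np.array_equal(
            gne.fuse([1.0, 2.0], [3.0, 4.0], 0.5), [1.0, 2.0, 1.5, 2.0]
        )
        assert np.array_equal(gne.fuse([1.0], [5.0], 0.0), [1.0, 0.0])
        assert np.array_equal(gne.fuse([1.0], [5.0], 1.0), [1.0, 5.0])
        with pytest.raises(ValueError):
            gne.fuse([1.0, 2.0], [1.0], 1.0)

    def test_hidden_forward_tanh_closed_form(self):
        h = gne.GNEHyper(d=2, k=1)
        p = init_params(h, 3, 0, seed=0)
        p.hidden[0].W = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        p.hidden[0].b = np.zeros(2)
        out = gne.hidden_forward(p, h, np.array([0.5, -0.5, 9.0, 9.0]))
        assert np.allclose(out, [math.tanh(0.5), math.tanh(-0.5)], atol=1e-12)
        p.hidden[0].W[:] = 0.0
        assert np.all(gne.hidden_forward(p, h, np.ones(4)) == 0.0)

    def test_hidden_forward_eval_mode_ignores_dropout(self):
        h = gne.GNEHyper(d=3, k=1, dropout=0.5)
        p = init_params(h, 3, 0, seed=0)
        fused = np.arange(6.0)
        a = gne.hidden_forward(p, h, fused, train_mode=False)
        b = gne.hidden_forward(p, h, fused, train_mode=False,
                               rng=np.random.default_rng(123))
        assert np.array_equal(a, b)

    def test_score_pair(self):
        assert gne.score_pair([1.0, 0.0], [0.0, 1.0]) == 0.0
        assert gne.score_pair([1.0, 2.0], [3.0, 4.0]) == 11.0
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(size=8)
        loop = sum(x * y for x, y in zip(a, b))
        assert abs(gne.score_pair(a, b) - loop) < 1e-12


class TestConditionalProb:
    def test_uniform_when_scores_equal(self):
        h = gne.GNEHyper(d=2, k=1)
        p = init_params(h, 5, 0, seed=0)
        p.W_out[:] = 0.0
        probs = gne.conditional_prob(p, h, np.zeros((5, 0)), 0)
        assert np.allclose(probs, 0.2, atol=1e-12)

    def test_two_gene_closed_form(self):
        h = gne.GNEHyper(d=1, k=1)
        p = init_params(h, 2, 0, seed=0)
        # pin the hidden output to 1.0, then scores are W_out rows
        p.hidden[0].W[:] = 0.0
        p.hidden[0].b = np.array([np.arctanh(0.5)])
        p.W_out = np.array([[0.0], [math.log(3.0) / 0.5]])
        probs = gne.conditional_prob(p, h, np.zeros((2, 0)), 0)
        assert np.allclose(probs, [0.25, 0.75], atol=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_sums_to_one_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(3, 20))
        E = int(rng.integers(0, 6))
        h = gne.GNEHyper(d=int(rng.integers(1, 6)), k=int(rng.integers(1, 3)))
        p = init_params(h, M, E, seed=seed)
        for _, arr in p.trainable():
            arr *= rng.uniform(0.5, 4.0)
        X = rng.normal(size=(M, E))
        probs = gne.conditional_prob(p, h, X, int(rng.integers(0, M)))
        assert abs(probs.sum() - 1.0) < 1e-8
        assert np.all(probs > 0)


class TestNoiseSampling:
    def test_path_graph_only_eligible_gene(self):
        net = gne.GeneNetwork(["a", "b", "c"], [(0, 1), (1, 2)])
        draws = gne.sample_noise_genes(net, 0, 10, rng=0)
        assert draws == [2] * 10

    def test_star_center_has_no_candidates(self):
        net = gne.GeneNetwork(list("abcde"), [(0, i) for i in range(1, 5)])
        with pytest.raises(ValueError, match="no eligible"):
            gne.sample_noise_genes(net, 0, 1, rng=0)

    def test_samples_avoid_neighborhood(self, tiny_net):
        rng = np.random.default_rng(0)
        sampler = NoiseSampler(tiny_net)
        draws = sampler.sample(np.array([0, 1, 2] * 10), 4, rng)
        for row, src in zip(draws, [0, 1, 2] * 10):
            for g in row:
                assert g != src and g not in tiny_net.neighbors[src]

    def test_frequency_matches_degree_power(self):
        # hub-and-chain graph: eligible genes for source 0 have degrees 1..3
        edges = [(1, 2), (2, 3), (3, 4), (3, 5), (0, 6)]
        net = gne.GeneNetwork([f"g{i}" for i in range(7)], edges)
        deg = net.degrees().astype(float)
        eligible = [1, 2, 3, 4, 5]  # not 0 itself, not its neighbor 6
        w = deg[eligible] ** 0.75
        expect = w / w.sum()
        rng = np.random.default_rng(8)
        sampler = NoiseSampler(net)
        n = 100_000
        draws = sampler.sample(np.zeros(n, dtype=int), 1, rng).ravel()
        counts = np.bincount(draws, minlength=7)[eligible]
        sd = np.sqrt(n * expect * (1 - expect))
        assert np.all(np.abs(counts - n * expect) < 3 * sd)


class TestLossAndGradients:
    def fixture(self, **kw):
        rng = np.random.default_rng(0)
        net = gne.GeneNetwork(
            [f"g{i}" for i in range(6)],
            [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)],
        )
        X = rng.normal(size=(6, 4))
        h = small_hyper(**kw)
        p = init_params(h, 6, 4, seed=1)
        batch = (np.array([0, 1, 2, 3]), np.array([1, 2, 3, 4]))
        neg = np.array([[3, 5], [4, 0], [5, 1], [0, 2]])
        return net, X, h, p, batch, neg

    def test_zero_params_closed_form(self):
        _, X, h, p, (pos_i, pos_j), _ = self.fixture(num_neg=5)
        for _, arr in p.trainable():
            arr[:] = 0.0
        neg = np.zeros((4, 5), dtype=int)
        loss, _ = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=False)
        assert abs(loss - 6 * math.log(2)) < 1e-12

    def test_lam_zero_kills_attribute_gradient(self):
        _, X, h, p, (pos_i, pos_j), neg = self.fixture(lam=0.0)
        _, grads = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=False)
        assert np.all(grads.W_att == 0.0)
        assert np.any(grads.W_id != 0.0)

    @pytest.mark.parametrize(
        "kw", [dict(), dict(k=2), dict(batch_norm=True), dict(lam=0.0)]
    )
    def test_gradients_match_finite_differences(self, kw):
        _, X, h, p, (pos_i, pos_j), neg = self.fixture(**kw)
        loss, grads = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=True)
        gmap = dict(grads.trainable())
        eps = 1e-5
        for name, arr in p.trainable():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                lp, _ = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=True)
                arr[ix] = orig - eps
                lm, _ = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=True)
                arr[ix] = orig
                num[ix] = (lp - lm) / (2 * eps)
            denom = max(np.abs(num).max(), np.abs(gmap[name]).max(), 1e-8)
            assert np.abs(num - gmap[name]).max() / denom < 1e-4, name

    def test_empty_batch_errors(self):
        _, X, h, p, _, _ = self.fixture()
        with pytest.raises(ValueError, match="empty"):
            loss_and_grads(p, h, X, np.array([], int), np.array([], int),
                           np.zeros((0, 2), int))

    def test_permutation_equivariance(self):
        """Relabeling genes by pi (inputs, params and noise draws mapped
        through pi) leaves the loss invariant and permutes the gradients."""
        net, X, h, p, (pos_i, pos_j), neg = self.fixture()
        loss, grads = loss_and_grads(p, h, X, pos_i, pos_j, neg, train_mode=False)
        rng = np.random.default_rng(9)
        pi = rng.permutation(6)  # new index of gene g is pi[g]
        inv = np.argsort(pi)
        p2 = copy.deepcopy(p)
        p2.W_id = p.W_id[:, inv]
        p2.W_out = p.W_out[inv]
        loss2, grads2 = loss_and_grads(
            p2, h, X[inv], pi[pos_i], pi[pos_j], pi[neg], train_mode=False
        )
        assert abs(loss - loss2) < 1e-12
        assert np.allclose(grads2.W_id, grads.W_id[:, inv], atol=1e-12)
        assert np.allclose(grads2.W_out, grads.W_out[inv], atol=1e-12)
        assert np.allclose(grads2.W_att, grads.W_att, atol=1e-12)


class TestTraining:
    @pytest.mark.parametrize("seed", range(5))
    def test_loss_decreases(self, seed):
        cfg = gne.SyntheticConfig(
            n_genes=30, n_modules=3, p_in=0.4, p_out=0.05, n_experiments=20, seed=17
        )
        net, expr, _ = gne.generate_dataset(cfg)
        net, expr = gne.align(net, expr)
        h = gne.GNEHyper(d=8, batch_size=16, epochs=20, num_neg=5,
                         learning_rate=0.01, seed=seed)
        _, hist = gne.train(net, expr, h, sorted(net.edges))
        assert len(hist) == h.epochs
        assert hist[-1] < hist[0]

    def test_deterministic_history_and_embeddings(self, small_dataset, fast_hyper):
        net, expr, _ = small_dataset
        edges = sorted(net.edges)[:60]
        p1, h1 = gne.train(net, expr, fast_hyper, edges)
        p2, h2 = gne.train(net, expr, fast_hyper, edges)
        assert np.max(np.abs(np.array(h1) - np.array(h2))) < 1e-10
        e1 = gne.final_embeddings(p1, net, expr, fast_hyper)
        e2 = gne.final_embeddings(p2, net, expr, fast_hyper)
        assert np.array_equal(e1.Y, e2.Y)

    def test_empty_training_set_errors(self, small_dataset, fast_hyper):
        net, expr, _ = small_dataset
        with pytest.raises(ValueError):
            gne.train(net, expr, fast_hyper, [])

    def test_misaligned_inputs_error(self, small_dataset, fast_hyper):
        net, expr, _ = small_dataset
        bad = gne.ExpressionMatrix(expr.genes[::-1], expr.values)
        with pytest.raises(ValueError, match="align"):
            gne.train(net, bad, fast_hyper, sorted(net.edges)[:5])

    def test_topology_only_equals_zeroed_expression(self, small_dataset):
        net, expr, _ = small_dataset
        edges = sorted(net.edges)[:60]
        h0 = gne.GNEHyper(d=8, batch_size=32, epochs=3, num_neg=3, lam=0.0, seed=5)
        h1 = gne.GNEHyper(d=8, batch_size=32, epochs=3, num_neg=3, lam=1.0, seed=5)
        zeroed = gne.ExpressionMatrix(list(expr.genes), np.zeros_like(expr.values))
        pa, ha = gne.train(net, expr, h0, edges)
        pb, hb = gne.train(net, zeroed, h1, edges)
        assert np.max(np.abs(np.array(ha) - np.array(hb))) < 1e-10
        ya = gne.final_embeddings(pa, net, expr, h0).Y
        yb = gne.final_embeddings(pb, net, zeroed, h1).Y
        assert np.max(np.abs(ya - yb)) < 1e-10


class TestFinalEmbeddings:
    def test_zero_params_zero_embeddings(self, tiny_net):
        h = small_hyper()
        p = init_params(h, tiny_net.M, 0, seed=0)
        for _, arr in p.trainable():
            arr[:] = 0.0
        expr = gne.ExpressionMatrix(list(tiny_net.genes), np.zeros((tiny_net.M, 0)))
        emb = gne.final_embeddings(p, tiny_net, expr, h)
        assert emb.Y.shape == (6, 3)
        assert np.all(emb.Y == 0.0)

    def test_matches_per_gene_recomputation(self, tiny_net):
        rng = np.random.default_rng(0)
        h = small_hyper()
        X = rng.normal(size=(6, 4))
        expr = gne.ExpressionMatrix(list(tiny_net.genes), X)
        p = init_params(h, 6, 4, seed=2)
        emb = gne.final_embeddings(p, tiny_net, expr, h)
        for i in range(6):
            v_s = gne.lookup_structure(p, i)
            v_a = gne.transform_attributes(p, X[i], h.attr_activation)
            h_i = gne.hidden_forward(p, h, gne.fuse(v_s, v_a, h.lam))
            assert np.allclose(emb.Y[i], h_i + p.W_out[i], atol=1e-12)


def test_adam_moves_toward_minimum_of_quadratic():
    """Adam on a toy quadratic via the shared update rule (sanity of moments)."""
    h = gne.GNEHyper(d=1, k=1)
    p = init_params(h, 2, 0, seed=0)
    p.W_out[:] = 4.0
    opt = Adam(p, lr=0.1)
    for _ in range(200):
        g = zero_grads(p)
        g.W_out[:] = 2 * p.W_out  # d/dx of x^2
        opt.step(p, g)
    assert np.all(np.abs(p.W_out) < 1e-2)
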