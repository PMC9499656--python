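import numpy as np
import pytest

from exprgat import (
    GATEncoder,
    HeadParams,
    head_embedding,
    init_heads,
    masked_attention,
    multi_head_embed,
    raw_attention_scores,
)
from exprgat.gat import leaky_relu, load_encoder, save_encoder

from conftest import random_adjacency


def naive_scores(X, W, a):
    """Eq.-by-eq. double loop: c_ij = a^T [W x_i || W x_j]."""
    n = X.shape[0]
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            c[i, j] = a @ np.concatenate([W @ X[i], W @ X[j]])
    return c


def naive_softmax(c, A, slope):
    n = c.shape[0]
    alpha = np.zeros_like(c)
    for i in range(n):
        nbrs = np.flatnonzero(A[i] > 0)
        e = np.exp(leaky_relu(c[i, nbrs], slope))
        alpha[i, nbrs] = e / e.sum()
    return alpha


def naive_head(X, W, alpha, act):
    n, p = X.shape[0], W.shape[0]
    out = np.zeros((n, p))
    for i in range(X.shape[0]):
        acc = np.zeros(p)
        for j in range(n):
            acc += alpha[i, j] * (W @ X[j])
        out[i] = act(acc)
    return out


class TestInitHeads:
    def test_deterministic(self):
        a = init_heads(5, 3, 2, seed=9)
        b = init_heads(5, 3, 2, seed=9)
        for ha, hb in zip(a, b):
            np.testing.assert_array_equal(ha.W, hb.W)
            np.testing.assert_array_equal(ha.a, hb.a)

    def test_heads_independent(self):
        h1, h2 = init_heads(4, 2, 2, seed=0)
        assert not np.allclose(h1.W, h2.W)

    def test_xavier_variance(self):
        m, p = 1000, 10
        heads = init_heads(m, p, 1, seed=3)
        var = heads[0].W.var()
        assert abs(var - 2.0 / (m + p)) < 0.1 * 2.0 / (m + p)

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            init_heads(0, 2, 1, seed=0)


class TestRawAttentionScores:
    def test_zero_attention_vector(self, rng):
        hp = HeadParams(W=rng.normal(size=(2, 3)), a=np.zeros(4))
        c = raw_attention_scores(rng.normal(size=(5, 3)), hp)
        np.testing.assert_array_equal(c, np.zeros((5, 5)))

    def test_hand_evaluation(self):
        # W=[2], a=(1,1), x1=1, x2=3: c12 = 2+6 = 8, c21 = 6+2 = 8, c11 = 4
        hp = HeadParams(W=np.array([[2.0]]), a=np.array([1.0, 1.0]))
        c = raw_attention_scores(np.array([[1.0], [3.0]]), hp)
        assert c[0, 1] == pytest.approx(8.0)
        assert c[1, 0] == pytest.approx(8.0)
        assert c[0, 0] == pytest.approx(4.0)
        assert c[1, 1] == pytest.approx(12.0)

    def test_matches_naive_loop(self, rng):
        X = rng.normal(size=(5, 4))
        hp = HeadParams(W=rng.normal(size=(3, 4)), a=rng.normal(size=6))
        np.testing.assert_allclose(
            raw_attention_scores(X, hp), naive_scores(X, hp.W, hp.a), atol=1e-9
        )

    def test_dimension_mismatch(self, rng):
        hp = HeadParams(W=rng.normal(size=(2, 3)), a=rng.normal(size=4))
        with pytest.raises(ValueError):
            raw_attention_scores(rng.normal(size=(5, 7)), hp)


class TestMaskedAttention:
    def test_self_only_row(self, rng):
        A = np.eye(4)
        alpha = masked_attention(rng.normal(size=(4, 4)), A)
        np.testing.assert_allclose(np.diag(alpha), 1.0)
        np.testing.assert_array_equal(alpha - np.diag(np.diag(alpha)), np.zeros((4, 4)))

    def test_equal_scores_uniform(self):
        A = np.ones((3, 3))
        alpha = masked_attention(np.full((3, 3), 1.7), A)
        np.testing.assert_allclose(alpha, np.full((3, 3), 1 / 3))

    def test_matches_explicit_oracle(self, rng):
        c = rng.normal(size=(6, 6))
        A = random_adjacency(rng, 6)
        alpha = masked_attention(c, A, slope=0.2)
        np.testing.assert_allclose(alpha, naive_softmax(c, A, 0.2), atol=1e-9)
        assert np.all(alpha[A == 0] == 0.0)  # exactly zero off support

    def test_rows_sum_to_one(self, rng):
        alpha = masked_attention(rng.normal(size=(8, 8)), random_adjacency(rng, 8))
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_row_rejected(self, rng):
        A = np.eye(3)
        A[1, 1] = 0.0
        with pytest.raises(ValueError):
            masked_attention(rng.normal(size=(3, 3)), A)


class TestHeadEmbedding:
    def test_self_attention_collapse(self, rng):
        X = rng.normal(size=(4, 3))
        hp = HeadParams(W=rng.normal(size=(2, 3)), a=rng.normal(size=4))
        out = head_embedding(X, hp, np.eye(4), activation="identity")
        np.testing.assert_allclose(out, X @ hp.W.T, atol=1e-12)

    def test_uniform_mean_aggregation(self, rng):
        X = rng.normal(size=(5, 3))
        hp = HeadParams(W=rng.normal(size=(2, 3)), a=rng.normal(size=4))
        alpha = np.full((5, 5), 1 / 5)
        out = head_embedding(X, hp, alpha, activation="identity")
        mean_row = (X @ hp.W.T).mean(axis=0)
        for i in range(5):
            np.testing.assert_allclose(out[i], mean_row, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        from exprgat.gat import ACTIVATIONS

        X = rng.normal(size=(5, 3))
        hp = HeadParams(W=rng.normal(size=(2, 3)), a=rng.normal(size=4))
        A = random_adjacency(rng, 5)
        alpha = masked_attention(raw_attention_scores(X, hp), A)
        elu = ACTIVATIONS["elu"][0]
        np.testing.assert_allclose(
            head_embedding(X, hp, alpha, "elu"), naive_head(X, hp.W, alpha, elu), atol=1e-9
        )


class TestMultiHeadEmbed:
    def test_single_head_degenerate(self, rng):
        X = rng.normal(size=(5, 4))
        heads = init_heads(4, 3, 1, seed=0)
        A = random_adjacency(rng, 5)
        Z = multi_head_embed(X, A, heads)
        alpha = masked_attention(raw_attention_scores(X, heads[0]), A)
        np.testing.assert_allclose(Z.values, head_embedding(X, heads[0], alpha), atol=1e-12)

    def test_duplicated_heads(self, rng):
        X = rng.normal(size=(4, 3))
        hp = init_heads(3, 2, 1, seed=1)[0]
        A = random_adjacency(rng, 4)
        Z = multi_head_embed(X, A, [hp, hp.copy(), hp.copy()])
        np.testing.assert_array_equal(Z.head_block(0), Z.head_block(1))
        np.testing.assert_array_equal(Z.head_block(0), Z.head_block(2))

    def test_composition_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        heads = init_heads(4, 3, 2, seed=5)
        A = random_adjacency(rng, 6)
        Z = multi_head_embed(X, A, heads)
        blocks = []
        for hp in heads:
            alpha = naive_softmax(naive_scores(X, hp.W, hp.a), A, 0.2)
            from exprgat.gat import ACTIVATIONS

            blocks.append(naive_head(X, hp.W, alpha, ACTIVATIONS["elu"][0]))
        np.testing.assert_allclose(Z.values, np.concatenate(blocks, axis=1), atol=1e-9)

    def test_empty_head_list(self, rng):
        with pytest.raises(ValueError):
            multi_head_embed(rng.normal(size=(3, 2)), np.eye(3), [])


class TestEncoderInvariants:
    def test_permutation_equivariance(self, rng):
        n = 7
        X = rng.normal(size=(n, 5))
        A = random_adjacency(rng, n)
        enc = GATEncoder.initialize(5, 3, 2, seed=2)
        perm = rng.permutation(n)
        Z = enc.forward(X, A)
        Zp = enc.forward(X[perm], A[np.ix_(perm, perm)])
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-6)

    def test_locality(self, rng):
        """Perturbing feature row j moves embedding row i only if j in N_i."""
        n = 6
        X = rng.normal(size=(n, 4))
        A = random_adjacency(rng, n)
        enc = GATEncoder.initialize(4, 2, 2, seed=0)
        Z = enc.forward(X, A)
        j = 3
        X2 = X.copy()
        X2[j] += rng.normal(size=4)
        Z2 = enc.forward(X2, A)
        changed = np.abs(Z2 - Z).max(axis=1) > 1e-12
        non_neighbors = np.flatnonzero(A[:, j] == 0)
        assert not changed[non_neighbors].any()

    def test_gradient_matches_finite_differences(self, rng):
        n, m, p, h = 5, 3, 2, 2
        X = rng.normal(size=(n, m))
        A = random_adjacency(rng, n)
        enc = GATEncoder.initialize(m, p, h, seed=4)
        T = rng.normal(size=(n, p * h))

        params = [q.copy() for q in enc.parameters()]

        def loss_at(plist):
            enc.set_parameters(plist)
            return float(np.sum(T * enc.forward(X, A)))

        enc.set_parameters(params)
        _, caches = enc.forward(X, A, need_cache=True)
        grads = enc.backward(T, X, A, caches)
        eps = 1e-6
        for gi, g in enumerate(grads):
            flat = g.ravel()
            # spot-check a handful of coordinates per parameter array
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                plus = [q.copy() for q in params]
                plus[gi].ravel()[idx] += eps
                minus = [q.copy() for q in params]
                minus[gi].ravel()[idx] -= eps
                num = (loss_at(plus) - loss_at(minus)) / (2 * eps)
                assert num == pytest.approx(flat[idx], abs=1e-5, rel=1e-4)

    def test_save_load_round_trip(self, tmp_path, rng):
        enc = GATEncoder.initialize(4, 3, 2, seed=8, slope=0.15, activation="elu")
        save_encoder(tmp_path / "m.npz", enc)
        back = load_encoder(tmp_path / "m.npz")
        assert back.slope == enc.slope and back.activation == enc.activation
        X = rng.normal(size=(5, 4))
        A = random_adjacency(rng, 5)
        np.testing.assert_array_equal(back.forward(X, A), enc.forward(X, A))
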