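"""Attention core: weights, heads, contexts, stacking."""

import numpy as np
import pytest

from crossdti import _autodiff as ad
from crossdti.attention import (AttentionBundle, ProjectionParams, attend,
                                attention_weights, cross_context,
                                init_projection, multihead_context, project,
                                self_context)
from crossdti.encoding import EmbeddingMatrix
from crossdti.model import DTIModel, ModelConfig


def emb(values, true_len=None):
    values = np.asarray(values, dtype=np.float32)
    mask = np.ones(values.shape[0], dtype=bool)
    if true_len is not None:
        mask[true_len:] = False
    return EmbeddingMatrix(values=ad.Tensor(values), mask=mask)


def identity_params(dim):
    eye = np.eye(dim, dtype=np.float32)
    return ProjectionParams(Wq=ad.Tensor(eye[None]), Wk=ad.Tensor(eye[None]),
                            Wv=ad.Tensor(eye[None]), W0=ad.Tensor(eye),
                            h=1, d=dim)


def brute_force_multihead(Yq, Ykv, params):
    """Per-head loop with plain NumPy softmax; independent of the
    batched graph implementation."""
    h, d = params.h, params.d
    heads, queries = [], []
    for i in range(h):
        Q = Yq @ params.Wq.data[i]
        K = Ykv @ params.Wk.data[i]
        V = Ykv @ params.Wv.data[i]
        scores = Q @ K.T / np.sqrt(d)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        heads.append(w @ V)
        queries.append(Q)
    mh = np.concatenate(heads, axis=1) @ params.W0.data
    return np.concatenate(queries, axis=1) + mh


class TestWeights:
    def test_zero_queries_give_uniform_weights(self):
        w = attention_weights(np.zeros((3, 2)), np.ones((5, 2)), d=2)
        np.testing.assert_allclose(w, 1 / 5, atol=1e-7)

    def test_scalar_softmax_example(self):
        w = attention_weights(np.array([[1.0, 0.0]]),
                              np.array([[1.0, 0.0], [0.0, 1.0]]), d=2)
        z = np.array([1 / np.sqrt(2), 0.0])
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(w[0], expected, rtol=1e-5)

    def test_rows_sum_to_one_and_in_open_interval(self):
        rng = np.random.default_rng(0)
        w = attention_weights(rng.standard_normal((6, 4)),
                              rng.standard_normal((9, 4)), d=4)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
        assert ((w > 0) & (w < 1)).all()

    def test_plain_d_scaling_option(self):
        Q = np.array([[2.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        w_sqrt = attention_weights(Q, K, d=4, scale_mode="sqrt")
        w_d = attention_weights(Q, K, d=4, scale_mode="d")
        assert w_sqrt[0, 0] > w_d[0, 0]  # weaker scaling flattens less


class TestAttend:
    def test_uniform_weights_average_values(self):
        V = np.arange(12, dtype=float).reshape(4, 3)
        out = attend(np.full((2, 4), 0.25), V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))

    def test_onehot_weights_copy_rows(self):
        V = np.arange(6, dtype=float).reshape(3, 2)
        w = np.array([[0, 0, 1.0], [1.0, 0, 0]])
        np.testing.assert_allclose(attend(w, V), V[[2, 0]])

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(1)
        w, V = rng.random((4, 5)), rng.standard_normal((5, 3))
        expected = np.zeros((4, 3))
        for i in range(4):
            for j in range(3):
                for t in range(5):
                    expected[i, j] += w[i, t] * V[t, j]
        np.testing.assert_allclose(attend(w, V), expected, rtol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            attend(np.ones((2, 3)), np.ones((4, 2)))


class TestProject:
    def test_identity_single_head_returns_embedding(self):
        x = np.arange(6, dtype=float).reshape(3, 2)
        out = project(emb(x), identity_params(2), "Q")
        np.testing.assert_allclose(out.data[0], x)

    def test_hand_computed_product(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[[0.0, 1.0], [1.0, 0.0]]])
        p = ProjectionParams(Wq=ad.Tensor(W), Wk=ad.Tensor(W),
                             Wv=ad.Tensor(W), W0=ad.Tensor(np.eye(2)),
                             h=1, d=2)
        np.testing.assert_allclose(project(emb(x), p, "K").data[0],
                                   [[2.0, 1.0], [4.0, 3.0]])

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            project(emb(np.ones((2, 3))), identity_params(2), "Q")


class TestContexts:
    def test_zero_values_leave_residual_only(self):
        rng = np.random.default_rng(2)
        p = init_projection(4, 4, h=2, d=2, rng=rng)
        p.Wv.data[:] = 0.0
        q, kv = emb(rng.standard_normal((3, 4))), emb(
            rng.standard_normal((5, 4)))
        bundle = cross_context(q, kv, p)
        queries = np.concatenate(
            [q.values.data @ p.Wq.data[i] for i in range(2)], axis=1)
        np.testing.assert_allclose(bundle.context.data, queries, atol=1e-6)

    def test_single_head_identity_oracle(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([[2.0, 0.0], [0.0, 2.0]])
        bundle = cross_context(emb(x), emb(y), identity_params(2))
        scores = x @ y.T / np.sqrt(2)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(bundle.weights[0], w, rtol=1e-5)
        np.testing.assert_allclose(bundle.context.data, x + w @ y,
                                   rtol=1e-5)

    def test_matches_brute_force_on_random_5x8(self):
        rng = np.random.default_rng(3)
        params = init_projection(8, 8, h=2, d=4, rng=rng)
        Yq, Ykv = rng.standard_normal((5, 8)), rng.standard_normal((5, 8))
        bundle = cross_context(emb(Yq), emb(Ykv), params)
        expected = brute_force_multihead(Yq.astype(np.float32),
                                         Ykv.astype(np.float32), params)
        np.testing.assert_allclose(bundle.context.data, expected,
                                   rtol=1e-4, atol=1e-5)

    def test_self_equals_cross_with_itself(self):
        rng = np.random.default_rng(4)
        p = init_projection(6, 6, h=3, d=2, rng=rng)
        x = emb(rng.standard_normal((4, 6)))
        a = self_context(x, p)
        b = cross_context(x, x, p)
        np.testing.assert_allclose(a.context.data, b.context.data)

    def test_self_attention_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = init_projection(6, 6, h=2, d=3, rng=rng)
        x = rng.standard_normal((5, 6))
        perm = rng.permutation(5)
        a = self_context(emb(x), p).context.data
        b = self_context(emb(x[perm]), p).context.data
        np.testing.assert_allclose(b, a[perm], rtol=1e-4, atol=1e-5)

    def test_masked_matches_manual_pad_removal(self):
        rng = np.random.default_rng(6)
        p = init_projection(6, 6, h=2, d=3, rng=rng)
        kv_full = rng.standard_normal((5, 6)).astype(np.float32)
        q = emb(rng.standard_normal((3, 6)))
        masked = cross_context(q, emb(kv_full, true_len=3), p, masked=True)
        trimmed = cross_context(q, emb(kv_full[:3]), p, masked=False)
        np.testing.assert_allclose(masked.context.data,
                                   trimmed.context.data, rtol=1e-4,
                                   atol=1e-5)


class TestStacking:
    @pytest.mark.parametrize("arch,depth", [("CA_DP", 1), ("CA2_DP", 2),
                                            ("CA3_DP", 3)])
    def test_depth_matches_architecture(self, arch, depth):
        cfg = ModelConfig(architecture=arch, n_labels_drug=10,
                          n_labels_protein=10, max_len_drug=8,
                          max_len_protein=12, hidden_size=16, n_heads=2,
                          pool_width=2)
        model = DTIModel(cfg, np.random.default_rng(0))
        assert len(model.layers) == depth

    def test_parameter_count_grows_linearly_with_depth(self):
        def count(arch):
            cfg = ModelConfig(architecture=arch, n_labels_drug=10,
                              n_labels_protein=10, max_len_drug=8,
                              max_len_protein=12, hidden_size=16,
                              n_heads=2, pool_width=2)
            m = DTIModel(cfg, np.random.default_rng(0))
            return sum(p.data.size
                       for layer in m.layers
                       for side in ("p", "d")
                       for p in layer[side].parameters)

        c1, c2, c3 = count("CA_DP"), count("CA2_DP"), count("CA3_DP")
        assert c2 - c1 == c3 - c2
        assert c2 == 2 * c1

    def test_unsupported_depth_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            ModelConfig(architecture="CA4_DP")

    def test_batched_context_row_counts_match_sequence_lengths(self):
        cfg = ModelConfig(architecture="CA_DP", n_labels_drug=12,
                          n_labels_protein=12, max_len_drug=50,
                          max_len_protein=545, hidden_size=16, n_heads=2,
                          pool_width=2)
        model = DTIModel(cfg, np.random.default_rng(0))
        Xd = np.ones((2, 50), dtype=np.int32)
        Xp = np.ones((2, 545), dtype=np.int32)
        _, info = model.forward(Xd, Xp)
        # protein-query weights: 545 query rows x 50 key columns
        assert info["protein_weights"].shape == (2, 2, 545, 50)
        assert info["drug_weights"].shape == (2, 2, 50, 545)
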